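"""Closest-point 3D thickness, slice-wise 2D thickness, and the voxel oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminamap.laminar_thickness import (MeshDistanceQuery, ThicknessMap,
                                         closest_point_on_triangles,
                                         oracle_deviation, thickness_2d_slicewise,
                                         thickness_3d, thickness_oracle,
                                         transfer_map)
from laminamap.surface_extract import TriMesh
from laminamap.volume_io import BACKGROUND, GRANULAR, LabelVolume, WM

from .conftest import FOLIA_SPEC, icosphere


def _plane_mesh(z, extent, n=12):
    """Triangulated square plane at height z spanning [-extent, extent]^2."""
    g = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(g, g, indexing="ij")
    verts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            k = i * n + j
            faces.append([k, k + n, k + 1])
            faces.append([k + 1, k + n, k + n + 1])
    return TriMesh(vertices=verts, faces=np.asarray(faces))


class TestClosestPoint:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_point_triangle_distance_matches_dense_sampling(self, seed):
        """The analytic closest point beats (to sampling tolerance) every point
        of a dense barycentric sampling of the triangle."""
        rng = np.random.default_rng(seed)
        tri = rng.normal(size=(1, 3, 3))
        p = rng.normal(size=(1, 3)) * 2
        cp = closest_point_on_triangles(p, tri)
        d = np.linalg.norm(p - cp, axis=1)[0]
        u = np.linspace(0, 1, 60)
        uu, vv = np.meshgrid(u, u)
        keep = uu + vv <= 1
        pts = (np.outer((1 - uu - vv)[keep], tri[0, 0]) +
               np.outer(uu[keep], tri[0, 1]) + np.outer(vv[keep], tri[0, 2]))
        d_dense = np.linalg.norm(pts - p, axis=1).min()
        edge = max(np.linalg.norm(tri[0, 1] - tri[0, 0]),
                   np.linalg.norm(tri[0, 2] - tri[0, 0]),
                   np.linalg.norm(tri[0, 2] - tri[0, 1]))
        assert d <= d_dense + 1e-12
        assert d >= d_dense - edge / 59  # sampling resolution bound

    def test_query_equals_exhaustive_minimum(self):
        """The accelerated query must equal the brute-force minimum over all
        triangles — the index is pruning, never approximation."""
        target = icosphere(2, scale=(1.0, 0.7, 1.2))
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(64, 3)) * 1.5
        query = MeshDistanceQuery(target)
        fast = query.distances(pts)
        tri = target.triangles
        brute = np.empty(len(pts))
        for i, p in enumerate(pts):
            cp = closest_point_on_triangles(np.repeat(p[None], len(tri), axis=0), tri)
            brute[i] = np.linalg.norm(cp - p, axis=1).min()
        assert np.allclose(fast, brute, atol=1e-12)

    def test_distance_bounded_by_vertex_distance(self, shell_meshes):
        """Point-to-triangle distance can never exceed vertex-to-vertex search."""
        carrier = shell_meshes["purkinje_surface"]
        target = shell_meshes["wm_surface"]
        tmap = thickness_3d(carrier, target)
        from scipy.spatial import cKDTree
        vertex_d, _ = cKDTree(target.vertices).query(carrier.vertices)
        assert (tmap.thickness <= vertex_d + 1e-12).all()


class TestThickness3D:
    def test_concentric_spheres(self):
        carrier = icosphere(3, radius=6.0)
        target = icosphere(3, radius=5.0)
        tmap = thickness_3d(carrier, target)
        edge = np.linalg.norm(
            target.vertices[target.faces[:, 0]] - target.vertices[target.faces[:, 1]],
            axis=1).max()
        assert np.abs(tmap.thickness - 1.0).max() < edge

    def test_parallel_planes_exact(self):
        carrier = _plane_mesh(1.0, extent=1.0)
        target = _plane_mesh(0.0, extent=2.0)   # larger so projections stay interior
        tmap = thickness_3d(carrier, target)
        assert np.allclose(tmap.thickness, 1.0, atol=1e-12)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        carrier = icosphere(2, radius=2.0)
        target = icosphere(2, scale=(1.0, 0.8, 1.1))
        base = thickness_3d(carrier, target).thickness
        R = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        t = np.array([3.0, -1.0, 0.5])
        moved = thickness_3d(
            TriMesh(vertices=carrier.vertices @ R.T + t, faces=carrier.faces),
            TriMesh(vertices=target.vertices @ R.T + t, faces=target.faces)).thickness
        assert np.allclose(base, moved, atol=1e-9)

    def test_agrees_with_voxel_oracle_on_folia(self, folia_phantom, folia_granular_map):
        volume, _ = folia_phantom
        oracle = thickness_oracle(volume, "granular")
        diag = np.linalg.norm(volume.spacing)
        assert oracle_deviation(folia_granular_map, oracle) <= diag

    def test_empty_target_rejected(self):
        carrier = icosphere(1)
        with pytest.raises(ValueError, match="empty"):
            MeshDistanceQuery(TriMesh(vertices=np.empty((0, 3)), faces=np.empty((0, 3), dtype=int)))


def _slab_volume(normal, t=1.0, spacing=0.1, n=40):
    """WM / granular / background bands along direction ``normal``."""
    normal = np.asarray(normal, dtype=float)
    normal /= np.linalg.norm(normal)
    coords = np.arange(n) * spacing
    x, y, z = np.meshgrid(coords, coords, coords, indexing="ij")
    d = normal[0] * x + normal[1] * y + normal[2] * z
    mid = d.mean()
    grid = np.full((n, n, n), BACKGROUND, dtype=np.int16)
    grid[d < mid] = WM
    grid[(d >= mid) & (d < mid + t)] = GRANULAR
    return LabelVolume(grid=grid, spacing=(spacing,) * 3)


class TestThickness2D:
    def test_in_plane_slab_equals_true_thickness(self):
        vol = _slab_volume([1, 0, 0], t=1.0)       # normal perpendicular to z axis
        st2 = thickness_2d_slicewise(vol, "granular", axis=2)
        assert np.median(st2.valid_values()) == pytest.approx(1.0, abs=1e-9)

    def test_tilted_slab_stretches_by_inverse_sine(self):
        # normal at 30 degrees to the slicing axis -> in-slice width t / sin(30) = 2t
        normal = [np.sin(np.radians(30)), 0, np.cos(np.radians(30))]
        vol = _slab_volume(normal, t=1.0, n=60)
        st2 = thickness_2d_slicewise(vol, "granular", axis=2)
        assert np.median(st2.valid_values()) == pytest.approx(2.0, abs=vol.spacing[0])

    def test_2d_exceeds_3d_on_phantom_all_axes(self, folia_phantom, folia_granular_map):
        volume, _ = folia_phantom
        median_3d = np.median(folia_granular_map.valid_values())
        for axis in range(3):
            st2 = thickness_2d_slicewise(volume, "granular", axis)
            assert np.median(st2.valid_values()) >= median_3d - np.linalg.norm(volume.spacing)

    def test_slices_without_outer_boundary_marked_invalid(self):
        vol = _slab_volume([1, 0, 0], t=1.0, n=20)
        # remove all background in one z-slice: the outer interface vanishes there
        vol.grid[:, :, 5][vol.grid[:, :, 5] == BACKGROUND] = GRANULAR
        st2 = thickness_2d_slicewise(vol, "granular", axis=2)
        in_slice = st2.indices[:, 2] == 5
        assert in_slice.any()
        assert not st2.valid[in_slice].any()
        assert np.isnan(st2.thickness[in_slice]).all()


class TestOracle:
    def test_flat_slab(self):
        vol = _slab_volume([0, 0, 1], t=1.0)
        oracle = thickness_oracle(vol, "granular")
        assert np.abs(oracle.thickness - 1.0).max() <= 0.1 + 1e-9

    def test_shell_granular_near_truth(self, shell_phantom):
        volume, truth = shell_phantom
        oracle = thickness_oracle(volume, "granular")
        t_g = truth.layer_thickness["granular"]
        assert np.abs(np.median(oracle.thickness) - t_g) <= max(volume.spacing)

    def test_layer_absent_rejected(self):
        vol = LabelVolume(grid=np.ones((5, 5, 5), dtype=np.int16), spacing=(0.1,) * 3)
        with pytest.raises(ValueError, match="absent"):
            thickness_oracle(vol, "granular")


class TestTransfer:
    def test_identity_on_same_mesh(self, shell_granular_map):
        out = transfer_map(shell_granular_map, shell_granular_map.carrier)
        assert np.array_equal(out.thickness, shell_granular_map.thickness)
        assert np.array_equal(out.valid, shell_granular_map.valid)

    def test_constant_stays_constant(self, shell_meshes):
        carrier = shell_meshes["purkinje_surface"]
        const = ThicknessMap(carrier=carrier,
                             thickness=np.full(carrier.n_vertices, 0.7),
                             valid=np.ones(carrier.n_vertices, dtype=bool))
        out = transfer_map(const, shell_meshes["pial_surface"])
        assert np.allclose(out.thickness, 0.7)

    def test_transfer_bounded_by_source_variation(self, shell_granular_map, shell_meshes):
        out = transfer_map(shell_granular_map, shell_meshes["pial_surface"])
        src = shell_granular_map.thickness
        assert out.thickness.min() >= src.min() - 1e-12
        assert out.thickness.max() <= src.max() + 1e-12
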