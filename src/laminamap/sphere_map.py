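"""Conformal spherical parameterization of genus-zero surfaces.

A discrete conformal map in the Angenent–Haker class: solve the sparse
cotangent-Laplace equation ``L z = b`` with a dipole right-hand side supported
on one "pole" triangle (the derivative of a delta function in the pole
triangle's own conformal frame), interpret the complex solution as planar
coordinates, and carry the plane onto the unit sphere by inverse stereographic
projection.  One linear solve, deterministic, no iteration — the pole triangle
maps to the neighbourhood of the projection pole.

Angle fidelity is diagnosed per triangle by the ratio of singular values of
the linear map taking each source triangle to its image (1 = perfectly
conformal); this quantity is invariant under the Möbius transformations that
make the spherical image non-unique.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csc_matrix
from scipy.sparse.linalg import splu

from .laminar_thickness import ThicknessMap
from .surface_extract import TriMesh, connected_components

__all__ = [
    "SphericalMap", "conformal_flatten", "quasi_conformal_distortion",
    "texture_thickness", "cap_boundaries", "TexturedSphere",
]


@dataclass
class SphericalMap:
    """Unit-sphere coordinates per source vertex, connectivity preserved."""

    source: TriMesh
    sphere_coords: np.ndarray           # (n, 3), unit norm
    distortion: np.ndarray              # per-triangle quasi-conformal ratio >= 1

    @property
    def sphere_mesh(self) -> TriMesh:
        return TriMesh(vertices=self.sphere_coords, faces=self.source.faces,
                       name=f"{self.source.name}_sphere")


def _cotangent_laplacian(mesh: TriMesh) -> csc_matrix:
    """Half-cotangent-weight Laplacian (positive semi-definite, dense diagonal)."""
    v, f = mesh.vertices, mesh.faces
    rows, cols, vals = [], [], []
    for a_i, b_i, c_i in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # cotangent of the angle at corner c, weighting edge (a, b)
        a, b, c = f[:, a_i], f[:, b_i], f[:, c_i]
        u, w = v[a] - v[c], v[b] - v[c]
        cross = np.linalg.norm(np.cross(u, w), axis=1)
        cross = np.where(cross < 1e-300, 1e-300, cross)
        cot = np.einsum("ij,ij->i", u, w) / cross
        half = 0.5 * cot
        rows += [a, b, a, b]
        cols += [b, a, a, b]
        vals += [-half, -half, half, half]
    n = mesh.n_vertices
    rows, cols = np.concatenate(rows), np.concatenate(cols)
    vals = np.concatenate(vals)
    return coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


def _pole_rhs(mesh: TriMesh, pole_triangle: int) -> np.ndarray:
    """Complex dipole right-hand side: gradients of the three hat functions of
    the pole triangle expressed in the triangle's own orthonormal 2D frame."""
    tri = mesh.vertices[mesh.faces[pole_triangle]]
    e1, e2 = tri[1] - tri[0], tri[2] - tri[0]
    normal = np.cross(e1, e2)
    nn = np.linalg.norm(normal)
    if nn < 1e-300:
        raise ValueError("degenerate pole triangle")
    u_hat = e1 / np.linalg.norm(e1)
    v_hat = np.cross(normal / nn, u_hat)
    E = np.array([[e1 @ u_hat, e2 @ u_hat],
                  [e1 @ v_hat, e2 @ v_hat]])        # columns: edges in 2D
    Einv = np.linalg.inv(E)
    grad_b, grad_c = Einv[0], Einv[1]               # gradients of hats at B, C
    grad_a = -grad_b - grad_c
    b = np.zeros(mesh.n_vertices, dtype=complex)
    for vid, g in zip(mesh.faces[pole_triangle], (grad_a, grad_b, grad_c)):
        b[vid] += complex(g[0], g[1])
    return b


def conformal_flatten(mesh: TriMesh, pole_triangle: int | None = None) -> SphericalMap:
    """Map a closed genus-zero mesh conformally onto the unit sphere.

    ``pole_triangle`` defaults to the triangle whose centroid is farthest from
    the mesh centroid.  Raises on open, multi-component or non-genus-zero
    input, reporting the Euler characteristic.
    """
    if len(connected_components(mesh)) != 1:
        raise ValueError("mesh must be a single connected component")
    if not mesh.is_closed():
        raise ValueError(f"mesh is not closed ({len(mesh.boundary_edges())} boundary edges)")
    chi = mesh.euler_characteristic()
    if chi != 2:
        raise ValueError(f"mesh is not genus zero: Euler characteristic {chi} != 2")

    centroids = mesh.triangles.mean(axis=1)
    if pole_triangle is None:
        pole_triangle = int(np.argmax(np.linalg.norm(centroids - mesh.vertices.mean(axis=0), axis=1)))

    L = _cotangent_laplacian(mesh)
    b = _pole_rhs(mesh, pole_triangle)

    # L is singular (constants); pin the vertex farthest from the pole, which
    # maps near the image origin, and solve the reduced real systems once.
    pole_centroid = centroids[pole_triangle]
    pin = int(np.argmax(np.linalg.norm(mesh.vertices - pole_centroid, axis=1)))
    keep = np.ones(mesh.n_vertices, dtype=bool)
    keep[pin] = False
    L_red = L[np.ix_(keep, keep)].tocsc()
    solver = splu(L_red)
    z = np.zeros(mesh.n_vertices, dtype=complex)
    z[keep] = solver.solve(b[keep].real) + 1j * solver.solve(b[keep].imag)

    # Any uniform scale of the plane is a Möbius transform of the sphere; pick
    # the one balancing the two image hemispheres.
    scale = np.median(np.abs(z))
    if scale > 0:
        z = z / scale
    x, y = z.real, z.imag
    denom = 1.0 + x * x + y * y
    coords = np.column_stack([2 * x / denom, 2 * y / denom, (denom - 2) / denom])
    coords /= np.linalg.norm(coords, axis=1, keepdims=True)

    sphere = SphericalMap(source=mesh, sphere_coords=coords,
                          distortion=np.empty(len(mesh.faces)))
    sphere.distortion = quasi_conformal_distortion(mesh, sphere)
    return sphere


def _triangle_frames(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Per-triangle 2x2 edge matrices in a local orthonormal frame."""
    tri = vertices[faces]
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    n = np.cross(e1, e2)
    nn = np.linalg.norm(n, axis=1, keepdims=True)
    nn = np.where(nn < 1e-300, 1e-300, nn)
    e1n = np.linalg.norm(e1, axis=1, keepdims=True)
    e1n = np.where(e1n < 1e-300, 1e-300, e1n)
    u = e1 / e1n
    v = np.cross(n / nn, u)
    E = np.empty((len(faces), 2, 2))
    E[:, 0, 0] = np.einsum("ij,ij->i", e1, u)
    E[:, 0, 1] = np.einsum("ij,ij->i", e2, u)
    E[:, 1, 0] = np.einsum("ij,ij->i", e1, v)
    E[:, 1, 1] = np.einsum("ij,ij->i", e2, v)
    return E


def quasi_conformal_distortion(source: TriMesh, smap: SphericalMap | TriMesh) -> np.ndarray:
    """Per-triangle singular-value ratio of the source->image linear map.

    1 means the triangle is mapped conformally (similarity); degenerate image
    triangles are flagged infinite.
    """
    image = smap.sphere_mesh if isinstance(smap, SphericalMap) else smap
    if not np.array_equal(source.faces, image.faces):
        raise ValueError("source and image must share connectivity")
    Es = _triangle_frames(source.vertices, source.faces)
    Ei = _triangle_frames(image.vertices, image.faces)
    det_s = Es[:, 0, 0] * Es[:, 1, 1] - Es[:, 0, 1] * Es[:, 1, 0]
    det_i = Ei[:, 0, 0] * Ei[:, 1, 1] - Ei[:, 0, 1] * Ei[:, 1, 0]
    ok = (np.abs(det_s) > 1e-300) & (np.abs(det_i) > 1e-300)
    out = np.full(len(source.faces), np.inf)
    if ok.any():
        M = np.einsum("nij,njk->nik", Ei[ok], np.linalg.inv(Es[ok]))
        sv = np.linalg.svd(M, compute_uv=False)
        with np.errstate(divide="ignore"):
            out[ok] = sv[:, 0] / sv[:, 1]
    return out


@dataclass
class TexturedSphere:
    """Spherical mesh carrying a per-vertex thickness texture."""
    mesh: TriMesh
    thickness: np.ndarray
    valid: np.ndarray


def texture_thickness(smap: SphericalMap, tmap: ThicknessMap) -> TexturedSphere:
    """Attach a thickness map to the spherical coordinates of its carrier."""
    src = smap.source
    if tmap.carrier.n_vertices != src.n_vertices or not np.allclose(
            tmap.carrier.vertices, src.vertices):
        raise ValueError("thickness carrier does not match the flattened mesh")
    return TexturedSphere(mesh=smap.sphere_mesh, thickness=tmap.thickness.copy(),
                          valid=tmap.valid.copy())


def _boundary_loops(mesh: TriMesh) -> list[list[int]]:
    edges = mesh.boundary_edges()
    if len(edges) == 0:
        return []
    neighbours: dict[int, list[int]] = {}
    for a, b in edges:
        neighbours.setdefault(int(a), []).append(int(b))
        neighbours.setdefault(int(b), []).append(int(a))
    loops, seen = [], set()
    for start in sorted(neighbours):
        if start in seen:
            continue
        loop, prev, cur = [start], None, start
        seen.add(start)
        while True:
            nxt = [v for v in neighbours[cur] if v != prev and v not in seen]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            loop.append(cur)
            seen.add(cur)
        loops.append(loop)
    return loops


def cap_boundaries(mesh: TriMesh) -> tuple[TriMesh, np.ndarray]:
    """Close every boundary loop with a centroid fan.

    Returns the closed mesh and a boolean mask flagging the added cap centroid
    vertices, so downstream textures can mark them invalid.
    """
    loops = _boundary_loops(mesh)
    if not loops:
        return mesh, np.zeros(mesh.n_vertices, dtype=bool)
    vertices = [mesh.vertices]
    faces = [mesh.faces]
    n = mesh.n_vertices
    for loop in loops:
        centroid = mesh.vertices[loop].mean(axis=0)
        vertices.append(centroid[None, :])
        ring = np.asarray(loop)
        fan = np.column_stack([ring, np.roll(ring, -1), np.full(len(ring), n)])
        faces.append(fan)
        n += 1
    closed = TriMesh(vertices=np.vstack(vertices), faces=np.vstack(faces),
                     name=mesh.name)
    is_cap = np.zeros(closed.n_vertices, dtype=bool)
    is_cap[mesh.n_vertices:] = True
    return closed, is_cap
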