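"""Synthetic layered-cortex phantoms with analytic / quadrature ground truth.

Two geometries are provided:

``shell``
    Concentric spherical shells: white matter ball of radius ``r``, a granular
    band of thickness ``t_g`` and a molecular band of thickness ``t_m`` on top.
    Every ground-truth quantity is closed form (sphere areas, shell volumes),
    and the true normal thickness of each layer is constant.

``folia-slab``
    A folded ribbon mimicking cerebellar folia: the white-matter top surface is
    the extruded sine ``z = h0 + A sin(2 pi x / w)`` (``w`` defaults to 0.9 mm,
    the width of a typical cerebellar folium), and the granular / molecular
    layers are bands of the Euclidean distance to that curve.  Because the
    layers are distance level sets, the true closest-point thickness of the
    granular layer is exactly ``t_g`` at every point of the granular/molecular
    interface, *even where the bands merge inside tight troughs* — merging only
    removes parts of the outer interfaces, as real sulci do.  Interface areas
    and layer volumes are computed by marching-squares quadrature on a fine 2D
    distance field and are therefore valid under merging as well.

Lobules partition the phantom (azimuthal sectors for the shell, contiguous
x-blocks for the folia ribbon); ground truth is bookkept per lobule so that
per-lobule sums equal totals by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

from .volume_io import BACKGROUND, GRANULAR, LAYER_LABELS, MOLECULAR, WM, LabelVolume

__all__ = [
    "PhantomSpec", "PhantomGroundTruth",
    "make_shell_phantom", "make_folia_phantom",
    "inject_erosion", "shrink_phantom", "make_lobule_volume",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic layered-cortex volume.

    All lengths in mm.  ``voxel_spacing`` must resolve the thinnest layer with
    at least three voxels, otherwise downstream thickness estimates are
    meaningless and the spec is rejected.
    """

    geometry_kind: str = "shell"          # "shell" | "folia-slab"
    wm_radius: float = 5.0
    slab_base_height: float = 0.6
    granular_thickness: float = 0.5
    molecular_thickness: float = 0.3
    fold_amplitude: float = 0.25
    fold_wavelength: float = 0.9          # width of a typical folium
    domain_extent: tuple[float, float, float] | None = None
    voxel_spacing: float = 0.1
    n_lobules: int = 2
    erosion_fraction: float = 0.0
    shrink_factor: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.geometry_kind not in ("shell", "folia-slab"):
            raise ValueError(f"geometry_kind must be 'shell' or 'folia-slab', got {self.geometry_kind!r}")
        if self.granular_thickness <= 0 or self.molecular_thickness <= 0:
            raise ValueError("layer thicknesses must be > 0")
        if self.voxel_spacing <= 0:
            raise ValueError("voxel_spacing must be > 0")
        min_t = min(self.granular_thickness, self.molecular_thickness)
        if self.voxel_spacing > min_t / 3 + 1e-9:
            raise ValueError(
                f"voxel_spacing {self.voxel_spacing} must be <= min layer thickness / 3 "
                f"(= {min_t / 3:.4g}) so layers are resolvable")
        if not 0 <= self.erosion_fraction <= 1:
            raise ValueError("erosion_fraction must lie in [0, 1]")
        if self.shrink_factor < 1:
            raise ValueError("shrink_factor must be >= 1")
        if self.n_lobules < 1:
            raise ValueError("n_lobules must be >= 1")
        if self.geometry_kind == "shell":
            if self.wm_radius <= 0:
                raise ValueError("wm_radius must be > 0")
            if self.domain_extent is not None:
                outer = self.wm_radius + self.granular_thickness + self.molecular_thickness
                if min(self.domain_extent) < 2 * outer:
                    raise ValueError("domain_extent too small to contain the outer radius")
        else:
            if self.fold_wavelength <= 0:
                raise ValueError("fold_wavelength must be > 0")
            if self.fold_amplitude < 0:
                raise ValueError("fold_amplitude must be >= 0")
            if self.slab_base_height <= self.fold_amplitude:
                raise ValueError("slab_base_height must exceed fold_amplitude")

    @property
    def outer_radius(self) -> float:
        return self.wm_radius + self.granular_thickness + self.molecular_thickness


@dataclass
class PhantomGroundTruth:
    """Analytic / quadrature ground truth accompanying a phantom volume."""

    interface_areas: dict[str, float]          # mm^2 per interface name
    layer_volumes: dict[str, float]            # mm^3 per layer name
    layer_thickness: dict[str, float]          # true normal thickness, mm
    lobule_pial_areas: dict[int, float] = field(default_factory=dict)
    lobule_gm_volumes: dict[int, float] = field(default_factory=dict)


def _shell_grid(spec: PhantomSpec):
    s = spec.voxel_spacing
    if spec.domain_extent is None:
        extent = 2 * spec.outer_radius + 6 * s
        extents = (extent, extent, extent)
    else:
        extents = spec.domain_extent
    shape = tuple(int(round(e / s)) for e in extents)
    return shape


def make_shell_phantom(spec: PhantomSpec) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Concentric-sphere phantom; closed-form ground truth."""
    spec.validate()
    if spec.geometry_kind != "shell":
        raise ValueError("make_shell_phantom requires geometry_kind='shell'")
    s = spec.voxel_spacing
    shape = _shell_grid(spec)
    center = (np.array(shape) - 1) / 2.0 * s
    idx = [np.arange(n) * s - c for n, c in zip(shape, center)]
    x, y, z = np.meshgrid(*idx, indexing="ij")
    r = np.sqrt(x * x + y * y + z * z)

    r1, r2, r3 = spec.wm_radius, spec.wm_radius + spec.granular_thickness, spec.outer_radius
    grid = np.zeros(shape, dtype=np.int16)
    grid[r < r1] = WM
    grid[(r >= r1) & (r < r2)] = GRANULAR
    grid[(r >= r2) & (r < r3)] = MOLECULAR
    volume = LabelVolume(grid=grid, spacing=(s, s, s), origin=(0.0, 0.0, 0.0))

    sphere = lambda rad: 4 * math.pi * rad ** 2
    ball = lambda rad: 4 / 3 * math.pi * rad ** 3
    n = spec.n_lobules
    pial = sphere(r3)
    gm = ball(r3) - ball(r1)
    truth = PhantomGroundTruth(
        interface_areas={"wm_surface": sphere(r1), "purkinje_surface": sphere(r2),
                         "pial_surface": pial},
        layer_volumes={"white_matter": ball(r1), "granular": ball(r2) - ball(r1),
                       "molecular": ball(r3) - ball(r2)},
        layer_thickness={"granular": spec.granular_thickness,
                         "molecular": spec.molecular_thickness},
        lobule_pial_areas={k + 1: pial / n for k in range(n)},
        lobule_gm_volumes={k + 1: gm / n for k in range(n)},
    )
    return volume, truth


def _folia_extents(spec: PhantomSpec) -> tuple[float, float, float]:
    if spec.domain_extent is not None:
        return tuple(spec.domain_extent)
    x_extent = 2 * spec.fold_wavelength
    y_extent = spec.fold_wavelength
    z_extent = (spec.slab_base_height + spec.fold_amplitude
                + spec.granular_thickness + spec.molecular_thickness
                + 4 * spec.voxel_spacing)
    return (x_extent, y_extent, z_extent)


def _signed_curve_distance(xs: np.ndarray, zs: np.ndarray, spec: PhantomSpec,
                           sample_step: float) -> np.ndarray:
    """Signed distance (positive above) from grid points (xs x zs) to the fold
    curve z = h0 + A sin(2 pi x / w), sampled densely and queried via KD-tree."""
    A, w, h0 = spec.fold_amplitude, spec.fold_wavelength, spec.slab_base_height
    pad = spec.granular_thickness + spec.molecular_thickness + 2 * spec.voxel_spacing + A
    t = np.arange(xs.min() - pad, xs.max() + pad + sample_step, sample_step)
    curve = np.column_stack([t, h0 + A * np.sin(2 * math.pi * t / w)])
    tree = cKDTree(curve)
    gx, gz = np.meshgrid(xs, zs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gz.ravel()])
    d, _ = tree.query(pts, workers=-1)
    f_at_x = h0 + A * np.sin(2 * math.pi * gx.ravel() / w)
    sign = np.where(pts[:, 1] > f_at_x, 1.0, -1.0)
    return (d * sign).reshape(gx.shape)


def _polyline_lengths_by_block(contour_mm: np.ndarray, block_edges: np.ndarray) -> np.ndarray:
    """Sum segment lengths of one polyline, binned by the x of segment midpoints."""
    seg = np.diff(contour_mm, axis=0)
    lengths = np.hypot(seg[:, 0], seg[:, 1])
    mid_x = 0.5 * (contour_mm[:-1, 0] + contour_mm[1:, 0])
    bins = np.clip(np.searchsorted(block_edges, mid_x, side="right") - 1,
                   0, len(block_edges) - 2)
    out = np.zeros(len(block_edges) - 1)
    np.add.at(out, bins, lengths)
    return out


def make_folia_phantom(spec: PhantomSpec, *, strict_curvature: bool = False,
                       quadrature_refine: int = 4) -> tuple[LabelVolume, PhantomGroundTruth]:
    """Folded-ribbon phantom built by signed-distance thresholding.

    Layers are bands of the distance to the sinusoidal white-matter surface,
    so the granular layer's closest-point thickness is exactly ``t_g``
    everywhere on its outer interface.  Interface areas and layer volumes come
    from marching-squares quadrature of the distance field at ``quadrature_refine``
    times the voxel resolution, attributed to lobules (contiguous x-blocks) by
    segment / cell midpoint.

    With ``strict_curvature=True`` the call rejects amplitude/wavelength
    combinations whose normal offsets self-intersect at the troughs
    (offset >= minimum radius of curvature); by default such geometries are
    allowed and simply produce merged bands.
    """
    spec.validate()
    if spec.geometry_kind != "folia-slab":
        raise ValueError("make_folia_phantom requires geometry_kind='folia-slab'")
    A, w = spec.fold_amplitude, spec.fold_wavelength
    t_total = spec.granular_thickness + spec.molecular_thickness
    if strict_curvature and A > 0:
        min_curv_radius = (w / (2 * math.pi)) ** 2 / A   # trough radius of curvature
        if t_total >= min_curv_radius:
            raise ValueError(
                f"offset distance {t_total:.3g} mm >= minimum radius of curvature "
                f"{min_curv_radius:.3g} mm: offsets self-intersect")

    s = spec.voxel_spacing
    extents = _folia_extents(spec)
    shape = tuple(max(2, int(round(e / s))) for e in extents)
    xs = np.arange(shape[0]) * s
    zs = np.arange(shape[2]) * s
    sample_step = s / 10
    sdf = _signed_curve_distance(xs, zs, spec, sample_step)   # (nx, nz)

    plane = np.zeros(sdf.shape, dtype=np.int16)
    plane[sdf <= 0] = WM
    plane[(sdf > 0) & (sdf <= spec.granular_thickness)] = GRANULAR
    plane[(sdf > spec.granular_thickness) & (sdf <= t_total)] = MOLECULAR
    grid = np.repeat(plane[:, None, :], shape[1], axis=1)
    volume = LabelVolume(grid=grid, spacing=(s, s, s), origin=(0.0, 0.0, 0.0))

    # --- ground truth by level-set quadrature on a refined 2D field ---
    h = s / quadrature_refine
    xf = np.arange(0, extents[0] - s / 2 + h / 2, h)
    zf = np.arange(0, extents[2] + h / 2, h)
    sdf_f = _signed_curve_distance(xf, zf, spec, sample_step)
    block_edges = np.linspace(xf.min() - 1e-9, xf.max() + 1e-9, spec.n_lobules + 1)

    # areas: contour length at each level x extruded ribbon width.  The mesh a
    # voxel grid can carry spans the (ny-1) inter-centre intervals, so that is
    # the width used for interface areas; volumes use the full ny voxels.
    y_area = (shape[1] - 1) * s
    y_vol = shape[1] * s
    levels = {"wm_surface": 0.0, "purkinje_surface": spec.granular_thickness,
              "pial_surface": t_total}
    areas: dict[str, float] = {}
    pial_blocks = np.zeros(spec.n_lobules)
    for name, level in levels.items():
        per_block = np.zeros(spec.n_lobules)
        for contour in measure.find_contours(sdf_f, level):
            per_block += _polyline_lengths_by_block(contour * h, block_edges)
        if name == "pial_surface":
            pial_blocks = per_block * y_area
        areas[name] = float(per_block.sum() * y_area)

    cell = h * h
    gx = xf[:, None] + np.zeros_like(zf)[None, :]
    gran_mask = (sdf_f > 0) & (sdf_f <= spec.granular_thickness)
    mol_mask = (sdf_f > spec.granular_thickness) & (sdf_f <= t_total)
    wm_mask = sdf_f <= 0
    gm_blocks = np.zeros(spec.n_lobules)
    for mask in (gran_mask, mol_mask):
        bins = np.clip(np.searchsorted(block_edges, gx[mask], side="right") - 1,
                       0, spec.n_lobules - 1)
        np.add.at(gm_blocks, bins, cell * y_vol)

    truth = PhantomGroundTruth(
        interface_areas=areas,
        layer_volumes={"white_matter": float(wm_mask.sum() * cell * y_vol),
                       "granular": float(gran_mask.sum() * cell * y_vol),
                       "molecular": float(mol_mask.sum() * cell * y_vol)},
        layer_thickness={"granular": spec.granular_thickness,
                         "molecular": spec.molecular_thickness},
        lobule_pial_areas={k + 1: float(pial_blocks[k]) for k in range(spec.n_lobules)},
        lobule_gm_volumes={k + 1: float(gm_blocks[k]) for k in range(spec.n_lobules)},
    )
    return volume, truth


def make_lobule_volume(volume: LabelVolume, spec: PhantomSpec) -> LabelVolume:
    """Lobule partition aligned with a phantom: azimuthal sectors about the z
    axis through the domain centre (shell) or contiguous x-blocks (folia).
    Only tissue voxels (non-background) receive a lobule id; background is 0."""
    spec.validate()
    n = spec.n_lobules
    shape = volume.shape
    s = np.asarray(volume.spacing)
    tissue = volume.grid != BACKGROUND
    lob = np.zeros(shape, dtype=np.int16)
    if spec.geometry_kind == "shell":
        center = (np.array(shape) - 1) / 2.0 * s
        x = np.arange(shape[0])[:, None, None] * s[0] - center[0]
        y = np.arange(shape[1])[None, :, None] * s[1] - center[1]
        angle = np.arctan2(np.broadcast_to(y, shape), np.broadcast_to(x, shape))
        sector = np.floor((angle + math.pi) / (2 * math.pi) * n).astype(np.int16)
        sector = np.clip(sector, 0, n - 1)
        lob[tissue] = sector[tissue] + 1
    else:
        x = np.arange(shape[0]) * s[0]
        edges = np.linspace(x.min() - 1e-9, x.max() + 1e-9, n + 1)
        block = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, n - 1)
        block3 = np.broadcast_to(block[:, None, None].astype(np.int16), shape)
        lob[tissue] = block3[tissue] + 1
    label_map = {0: "unassigned", **{k + 1: f"lobule_{k + 1}" for k in range(n)}}
    return LabelVolume(grid=lob, spacing=volume.spacing, origin=volume.origin,
                       label_map=label_map)


def inject_erosion(volume: LabelVolume, fraction: float, seed: int,
                   window_mm: float = 0.45) -> LabelVolume:
    """Tear the molecular layer off a proportion of out-facing crowns.

    Crowns are detected as plateaus of local maxima of the molecular-layer
    height map (max z per (x, y) column) under a maximum filter of half-width
    ``window_mm`` (default: half a folium width).  ``ceil(fraction * n_crowns)``
    crowns are drawn with a generator seeded by ``seed`` and every molecular
    voxel in the dilated crown columns is relabelled background — emulating
    tissue worn off at exposed folia tips.  White matter and granular labels
    are never modified.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must lie in [0, 1]")
    mol = volume.grid == MOLECULAR
    if not mol.any():
        raise ValueError("volume contains no molecular-layer voxels")
    out = volume.copy()
    if fraction == 0:
        return out

    height = np.where(mol.any(axis=2), mol.shape[2] - 1 - np.argmax(mol[:, :, ::-1], axis=2), -1)
    present = height >= 0
    k = max(3, int(round(window_mm / volume.spacing[0])))
    local_max = ndimage.maximum_filter(height, size=k, mode="nearest")
    crowns = present & (height == local_max)
    labelled, n_crowns = ndimage.label(crowns)
    if n_crowns == 0:
        return out
    n_remove = math.ceil(fraction * n_crowns)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(n_crowns, size=min(n_remove, n_crowns), replace=False) + 1

    columns = np.isin(labelled, chosen)
    columns = ndimage.binary_dilation(columns, iterations=max(1, k // 3))
    torn = mol & columns[:, :, None]
    out.grid[torn] = BACKGROUND
    return out


def shrink_phantom(volume: LabelVolume, shrink: float) -> LabelVolume:
    """Rescale the geometry by 1/``shrink`` about the volume centre, resampling
    labels onto the same grid by nearest neighbour — simulates isotropic tissue
    shrinkage so that measurement correction can be round-trip tested."""
    if shrink < 1:
        raise ValueError("shrink factor must be >= 1")
    out = volume.copy()
    if shrink == 1:
        return out
    center = (np.array(volume.shape) - 1) / 2.0
    matrix = np.diag([shrink] * 3)
    offset = center * (1 - shrink)
    out.grid = ndimage.affine_transform(
        volume.grid, matrix, offset=offset, order=0, mode="constant",
        cval=BACKGROUND, output=volume.grid.dtype)
    return out
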