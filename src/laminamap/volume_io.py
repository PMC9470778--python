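"""Label-volume container and NIfTI-1 I/O.

Conventions used throughout the package:

* grid axes are (x, y, z), 0-based indices;
* a voxel index ``i`` maps to world millimetres as ``origin + i * spacing``
  (voxel centres), per axis;
* layer volumes use the label vocabulary in :data:`LAYER_LABELS`; lobule
  volumes use contiguous positive integer ids with 0 = unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

BACKGROUND = 0
WM = 1
GRANULAR = 2   # includes the one-cell-thick Purkinje layer
MOLECULAR = 3

LAYER_LABELS = {
    BACKGROUND: "background",
    WM: "white_matter",
    GRANULAR: "granular",
    MOLECULAR: "molecular",
}

#: Lobule ids in conventional cerebellar report order.
LOBULE_NAMES = {
    1: "Lobules I, II", 2: "Lobule III", 3: "Lobule IV", 4: "Lobule V",
    5: "Lobule VI", 6: "Crus I", 7: "Crus II", 8: "Lobule VIIB",
    9: "Lobule VIIIA", 10: "Lobule VIIIB", 11: "Lobule IX", 12: "Lobule X",
    13: "Vermis VIII", 14: "Vermis IX", 15: "Vermis X",
}


@dataclass
class LabelVolume:
    """A 3D integer label grid with world spacing/origin in mm."""

    grid: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[int, str] = field(default_factory=lambda: dict(LAYER_LABELS))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValueError("grid must be a non-empty 3D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("grid must hold integer labels")
        self.spacing = tuple(float(s) for s in np.broadcast_to(self.spacing, (3,)))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = tuple(float(o) for o in np.broadcast_to(self.origin, (3,)))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def world_coords(self, indices: np.ndarray) -> np.ndarray:
        """Voxel indices (n, 3) -> world mm (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def labels_present(self) -> set[int]:
        return set(int(v) for v in np.unique(self.grid))

    def validate_labels(self, expected_labels: set[int] | None = None) -> None:
        allowed = set(self.label_map) if expected_labels is None else set(expected_labels)
        unknown = sorted(self.labels_present() - allowed)
        if unknown:
            raise ValueError(f"unexpected labels present: {unknown} (allowed: {sorted(allowed)})")

    def copy(self) -> "LabelVolume":
        return replace(self, grid=self.grid.copy(), label_map=dict(self.label_map))


def write_label_volume(volume: LabelVolume, path: str | Path) -> Path:
    """Write as NIfTI-1; spacing goes into the affine diagonal, origin into the
    translation.  The label vocabulary is stored in a ``.labels.json`` sidecar."""
    path = Path(path)
    affine = np.diag(list(volume.spacing) + [1.0])
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(volume.grid.astype(np.int16), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({str(k): v for k, v in volume.label_map.items()}, indent=1))
    return path


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".labels.json")
    return path.with_suffix(".labels.json")


def read_label_volume(path: str | Path,
                      expected_labels: set[int] | None = None) -> LabelVolume:
    """Read a NIfTI-1 label volume and validate its label vocabulary.

    Raises ``ValueError`` listing offending labels when a label outside
    ``expected_labels`` is present, and when the header carries no positive
    voxel spacing.
    """
    path = Path(path)
    img = nib.load(str(path))
    grid = np.asanyarray(img.dataobj)
    if not np.issubdtype(grid.dtype, np.integer):
        rounded = np.rint(grid)
        if not np.allclose(grid, rounded):
            raise ValueError(f"{path} does not contain integer labels")
        grid = rounded.astype(np.int32)
    zooms = img.header.get_zooms()[:3]
    if len(zooms) < 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"{path}: missing or non-positive voxel spacing in header")
    origin = tuple(float(v) for v in img.affine[:3, 3])

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        label_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
    else:
        label_map = {int(v): str(int(v)) for v in np.unique(grid)}
    volume = LabelVolume(grid=np.ascontiguousarray(grid), spacing=tuple(float(z) for z in zooms),
                         origin=origin, label_map=label_map)
    if expected_labels is not None:
        volume.validate_labels(expected_labels)
    return volume


def check_alignment(layers: LabelVolume, lobules: LabelVolume) -> bool:
    """Confirm two volumes share grid shape, spacing and origin.

    Returns True on success; raises ``ValueError`` naming the first differing
    attribute otherwise.
    """
    if layers.shape != lobules.shape:
        raise ValueError(f"alignment failure: shape {layers.shape} != {lobules.shape}")
    # NIfTI-1 stores zooms as float32; tolerance covers that representation
    if not np.allclose(layers.spacing, lobules.spacing, rtol=0, atol=1e-6):
        raise ValueError(f"alignment failure: spacing {layers.spacing} != {lobules.spacing}")
    if not np.allclose(layers.origin, lobules.origin, rtol=0, atol=1e-6):
        raise ValueError(f"alignment failure: origin {layers.origin} != {lobules.origin}")
    return True
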