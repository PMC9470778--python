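"""Shared fixtures: phantoms and their surfaces/maps, computed once per session."""

from __future__ import annotations

import numpy as np
import pytest
import trimesh

from laminamap.laminar_thickness import thickness_3d
from laminamap.phantom_forge import PhantomSpec, make_folia_phantom, make_shell_phantom
from laminamap.surface_extract import TriMesh, extract_canonical_surfaces


SHELL_SPEC = PhantomSpec(geometry_kind="shell", wm_radius=5.0, granular_thickness=1.0,
                         molecular_thickness=0.3, voxel_spacing=0.1, n_lobules=2)

# the folded-ribbon geometry exercised throughout: folium width 0.9 mm,
# amplitude 0.5 mm (deep folds, merged bands in the troughs)
FOLIA_SPEC = PhantomSpec(geometry_kind="folia-slab", granular_thickness=0.3,
                         molecular_thickness=0.3, fold_amplitude=0.5,
                         fold_wavelength=0.9, voxel_spacing=0.05,
                         slab_base_height=0.85, n_lobules=2)


@pytest.fixture(scope="session")
def shell_phantom():
    return make_shell_phantom(SHELL_SPEC)


@pytest.fixture(scope="session")
def shell_meshes(shell_phantom):
    volume, _ = shell_phantom
    return extract_canonical_surfaces(volume)


@pytest.fixture(scope="session")
def shell_granular_map(shell_meshes):
    return thickness_3d(shell_meshes["purkinje_surface"], shell_meshes["wm_surface"])


@pytest.fixture(scope="session")
def shell_molecular_map(shell_meshes):
    return thickness_3d(shell_meshes["purkinje_surface"], shell_meshes["pial_surface"])


@pytest.fixture(scope="session")
def folia_phantom():
    return make_folia_phantom(FOLIA_SPEC)


@pytest.fixture(scope="session")
def folia_meshes(folia_phantom):
    volume, _ = folia_phantom
    return extract_canonical_surfaces(volume)


@pytest.fixture(scope="session")
def folia_granular_map(folia_meshes):
    return thickness_3d(folia_meshes["purkinje_surface"], folia_meshes["wm_surface"])


def icosphere(subdivisions: int = 3, scale=(1.0, 1.0, 1.0), radius: float = 1.0) -> TriMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriMesh(vertices=np.asarray(m.vertices) * np.asarray(scale),
                   faces=np.asarray(m.faces))
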