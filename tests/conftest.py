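"""Shared fixtures: phantoms and assembled solver systems are session-scoped
because factorizing the diffusion operator dominates test runtime."""

import warnings

import numpy as np
import pytest

from nirscc.forward import (
    OpticalProperties,
    TissueOptics,
    assemble_diffusion_system,
    default_properties,
)
from nirscc.meshing import voxel_to_tetmesh
from nirscc.phantom import (
    PhantomSpec,
    TISSUE_LABELS,
    VoxelModel,
    build_sphere_phantom,
    place_fiducials_1010,
    place_landmarks,
)

#: homogeneous reference tissue of the semi-infinite validation (mu_s' = 1.0/mm)
HOMOG = TissueOptics(mu_a=0.01, mu_s=10.0, g=0.9, n=1.4)


def make_slab(extent_xy: float, depth: float, h: float) -> VoxelModel:
    """Homogeneous scalp-tissue slab with its free surface exactly at z = 0.

    Keeping the surface plane and the physical extents independent of the
    voxel size makes the continuum problem fixed under grid refinement (voxel
    centers sit at z = h/2, 3h/2, ...), which the convergence test relies on;
    pass extents divisible by h.
    """
    nx = int(round(extent_xy / h))
    nz = int(round(depth / h))
    labels = np.full((nx, nx, nz), TISSUE_LABELS["scalp"], np.int8)
    return VoxelModel(
        labels=labels,
        regions=np.zeros_like(labels, np.int32),
        voxel_size=h,
        origin=np.array([-(nx - 1) / 2 * h, -(nx - 1) / 2 * h, h / 2.0]),
    )


@pytest.fixture(scope="session")
def sphere40():
    """Five-layer sphere phantom, 40 mm outer radius, 2 mm voxels."""
    spec = PhantomSpec(outer_radius=40.0, voxel_size=2.0)
    model = build_sphere_phantom(spec)
    lm = place_landmarks(model)
    fids = place_fiducials_1010(model, lm)
    return spec, model, lm, fids


@pytest.fixture(scope="session")
def sphere40_mesh(sphere40):
    _, model, _, _ = sphere40
    return voxel_to_tetmesh(model)


@pytest.fixture(scope="session")
def sphere40_system(sphere40_mesh):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # CSF diffusion-validity warning
        return assemble_diffusion_system(sphere40_mesh, default_properties())


@pytest.fixture(scope="session")
def slab_system():
    """Homogeneous 84 x 84 x 33 mm slab at 2 mm voxels (semi-infinite proxy)."""
    model = make_slab(84.0, 33.0, 2.0)
    mesh = voxel_to_tetmesh(model)
    props = OpticalProperties(tissues={TISSUE_LABELS["scalp"]: HOMOG})
    return assemble_diffusion_system(mesh, props)


@pytest.fixture(scope="session")
def tiny_slab_system():
    """Small homogeneous slab for cheap solver unit tests."""
    model = make_slab(40.0, 20.0, 2.0)
    mesh = voxel_to_tetmesh(model)
    props = OpticalProperties(tissues={TISSUE_LABELS["scalp"]: HOMOG})
    return assemble_diffusion_system(mesh, props)
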