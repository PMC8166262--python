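"""Diffusion FEM operator, boundary model, and the semi-infinite oracle."""

import numpy as np
import pytest

from nirscc.forward import (
    OpticalProperties,
    PlacementError,
    SourceSpec,
    TissueOptics,
    analytic_semi_infinite,
    assemble_diffusion_system,
    default_properties,
    detected_intensity,
    internal_reflection_parameter,
    solve_fluence,
)
from nirscc.meshing import voxel_to_tetmesh
from nirscc.phantom import TISSUE_LABELS, VoxelModel

from conftest import HOMOG, make_slab


def test_tissue_optics_derived_quantities_and_validation():
    t = TissueOptics(mu_a=0.018, mu_s=19.0, g=0.9, n=1.4)
    assert t.mu_s_prime == pytest.approx(19.0 * 0.1)
    assert t.kappa == pytest.approx(1.0 / (3.0 * (0.018 + 1.9)))
    assert t.mu_eff == pytest.approx(np.sqrt(3 * 0.018 * (0.018 + 1.9)))
    with pytest.raises(ValueError):
        TissueOptics(mu_a=-1.0, mu_s=1.0, g=0.5, n=1.4)
    with pytest.raises(ValueError):
        TissueOptics(mu_a=0.01, mu_s=1.0, g=1.0, n=1.4)
    # mu_s' = mu_s (1 - g) holds exactly for the default table
    for optics in default_properties().tissues.values():
        assert optics.mu_s_prime == optics.mu_s * (1.0 - optics.g)


def test_matrix_symmetric_and_stiffness_partition_of_unity(tiny_slab_system):
    A = tiny_slab_system.matrix
    asym = abs(A - A.T).max()
    assert asym < 1e-14 * abs(A).max()
    # row sums reduce to the lumped absorption + Robin diagonals (stiffness
    # rows sum to zero by partition of unity of the P1 basis)
    ones = np.ones(A.shape[0])
    expected = (
        tiny_slab_system.node_mu_a * tiny_slab_system.mesh.nodal_volumes()
        + tiny_slab_system.robin_diagonal
    )
    assert np.allclose(A @ ones, expected, rtol=1e-10, atol=1e-12)


def test_all_tissue_property_sets_solvable():
    """Layered model with all five tissues: solve succeeds at tight residual."""
    labels = np.zeros((10, 10, 10), np.int8)
    for z, t in zip(range(0, 10, 2), ["wm", "gm", "csf", "skull", "scalp"]):
        labels[:, :, z : z + 2] = TISSUE_LABELS[t]
    model = VoxelModel(labels=labels, regions=np.zeros_like(labels, np.int32), voxel_size=1.0)
    mesh = voxel_to_tetmesh(model)
    with pytest.warns(UserWarning, match="diffusion approximation is marginal"):
        system = assemble_diffusion_system(mesh, default_properties())
    top = mesh.nodes[:, 2].max()
    field = solve_fluence(system, SourceSpec(np.array([0.0, 0.0, top])))
    # solve() raises if the relative residual exceeds 1e-8
    assert np.all(np.isfinite(field.values))


def test_missing_tissue_properties_raise(tiny_slab_system):
    model = make_slab(10.0, 6.0, 2.0)
    mesh = voxel_to_tetmesh(model)
    with pytest.raises(KeyError):
        assemble_diffusion_system(
            mesh, OpticalProperties(tissues={TISSUE_LABELS["gm"]: HOMOG})
        )


def test_fluence_strictly_positive(tiny_slab_system):
    zmin = tiny_slab_system.mesh.nodes[:, 2].min()
    field = solve_fluence(tiny_slab_system, SourceSpec(np.array([0.0, 0.0, zmin])))
    assert field.values.min() > 0.0


def test_reciprocity(tiny_slab_system):
    """Detected intensity is invariant under source-detector exchange."""
    zmin = tiny_slab_system.mesh.nodes[:, 2].min()
    a = np.array([-8.0, 0.0, zmin])
    b = np.array([7.0, 3.0, zmin])
    i_ab = detected_intensity(solve_fluence(tiny_slab_system, SourceSpec(a)), b)
    i_ba = detected_intensity(solve_fluence(tiny_slab_system, SourceSpec(b)), a)
    assert i_ab == pytest.approx(i_ba, rel=1e-6)


def test_detector_off_surface_raises(tiny_slab_system):
    field = solve_fluence(
        tiny_slab_system, SourceSpec(np.array([0.0, 0.0, tiny_slab_system.mesh.nodes[:, 2].min()]))
    )
    with pytest.raises(PlacementError):
        detected_intensity(field, np.array([0.0, 0.0, 200.0]))


def test_source_amplitude_scales_linearly(tiny_slab_system):
    zmin = tiny_slab_system.mesh.nodes[:, 2].min()
    pos = np.array([0.0, 0.0, zmin])
    f1 = solve_fluence(tiny_slab_system, SourceSpec(pos, amplitude=1.0))
    f3 = solve_fluence(tiny_slab_system, SourceSpec(pos, amplitude=3.0))
    assert np.allclose(f3.values, 3.0 * f1.values, rtol=1e-12)


def test_analytic_semi_infinite_properties():
    rhos = np.arange(5.0, 61.0, 1.0)
    vals = np.array([analytic_semi_infinite(HOMOG, r) for r in rhos])
    assert np.all(np.diff(vals) < 0)  # strictly decreasing in rho
    # asymptotic log-slope of rho^2 * R approaches -mu_eff within 2%
    far = (rhos >= 40) & (rhos <= 60)
    slope = np.polyfit(rhos[far], np.log(rhos[far] ** 2 * vals[far]), 1)[0]
    assert slope == pytest.approx(-HOMOG.mu_eff, rel=0.02)
    # doubling mu_a decreases reflectance
    darker = TissueOptics(mu_a=0.02, mu_s=10.0, g=0.9, n=1.4)
    assert analytic_semi_infinite(darker, 20.0) < analytic_semi_infinite(HOMOG, 20.0)
    with pytest.raises(ValueError):
        analytic_semi_infinite(HOMOG, 0.0)


def test_internal_reflection_parameter_value():
    # Groenhuis polynomial at n = 1.4 gives A ~ 3.25; A(1) ~ no mismatch boost
    assert internal_reflection_parameter(1.4) == pytest.approx(3.25, abs=0.05)
    assert internal_reflection_parameter(1.0) < internal_reflection_parameter(1.4)


def test_intensity_decreases_with_separation(slab_system):
    zmin = slab_system.mesh.nodes[:, 2].min()
    field = solve_fluence(slab_system, SourceSpec(np.array([0.0, 0.0, zmin])))
    vals = [
        detected_intensity(field, np.array([rho, 0.0, zmin]))
        for rho in (10.0, 15.0, 20.0, 25.0, 30.0)
    ]
    assert np.all(np.diff(vals) < 0)


def test_grid_refinement_convergence():
    """Halving the voxel changes the detected intensity by a shrinking amount."""
    intensities = {}
    for h in (4.0, 2.0, 1.0):
        model = make_slab(48.0, 20.0, h)
        mesh = voxel_to_tetmesh(model)
        props = OpticalProperties(tissues={TISSUE_LABELS["scalp"]: HOMOG})
        system = assemble_diffusion_system(mesh, props)
        zmin = mesh.nodes[:, 2].min()
        field = solve_fluence(system, SourceSpec(np.array([-7.5, 0.0, zmin])))
        intensities[h] = detected_intensity(field, np.array([7.5, 0.0, zmin]))
    e_coarse = abs(intensities[4.0] - intensities[2.0])
    e_fine = abs(intensities[2.0] - intensities[1.0])
    assert e_fine < e_coarse
    assert np.log2(e_coarse / e_fine) >= 1.0  # observed order >= 1
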