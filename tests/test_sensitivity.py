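"""SD-pair placement, PMDF fields, partial pathlengths and perturbation oracle."""

import numpy as np
import pytest

from nirscc.forward import OpticalProperties, SourceSpec, solve_fluence
from nirscc.meshing import voxel_to_tetmesh
from nirscc.phantom import TISSUE_LABELS
from nirscc.sensitivity import (
    compute_pmdf,
    partial_pathlength_perturbation,
    place_sd_pair,
    region_pathlengths,
    _perturbed_pathlength,
    _region_increment_mass,
)

from conftest import HOMOG, make_slab


def _geodesic_mm(fids, p, q):
    u = (p - fids.center) / fids.radius
    v = (q - fids.center) / fids.radius
    return fids.radius * np.arccos(np.clip(np.dot(u, v), -1, 1))


def test_sd_pair_geometry(sphere40):
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "Cz", "circumferential", 20.0)
    assert _geodesic_mm(fids, pair.source_position, fids["Cz"]) == pytest.approx(10.0, abs=1e-9)
    assert _geodesic_mm(fids, pair.detector_position, fids["Cz"]) == pytest.approx(10.0, abs=1e-9)
    assert _geodesic_mm(fids, pair.source_position, pair.detector_position) == pytest.approx(
        20.0, abs=1e-9
    )
    with pytest.raises(KeyError):
        place_sd_pair(fids, "XX", "circumferential", 20.0)
    with pytest.raises(ValueError):
        place_sd_pair(fids, "Cz", "diagonal", 20.0)


def test_orientations_orthogonal_on_sphere(sphere40):
    _, _, _, fids = sphere40
    for label in ("T4", "F3", "POz"):
        dirs = {}
        for orientation in ("circumferential", "vertical"):
            pair = place_sd_pair(fids, label, orientation, 10.0)
            d = pair.source_position - pair.detector_position
            dirs[orientation] = d / np.linalg.norm(d)
        cosang = abs(np.dot(dirs["circumferential"], dirs["vertical"]))
        assert cosang < np.sin(np.deg2rad(5.0))


def test_nested_distances_share_midpoint(sphere40):
    _, _, _, fids = sphere40
    for d in (10.0, 15.0, 20.0, 25.0, 30.0):
        pair = place_sd_pair(fids, "T4", "circumferential", d)
        mid = 0.5 * (pair.source_position + pair.detector_position)
        mid = fids.center + fids.radius * (mid - fids.center) / np.linalg.norm(mid - fids.center)
        assert np.allclose(mid, fids["T4"], atol=1e-9)


def test_pmdf_nonnegative_and_normalization(sphere40, sphere40_mesh, sphere40_system):
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "T4", "circumferential", 20.0)
    pmdf = compute_pmdf(sphere40_system, pair)
    assert np.all(pmdf.values >= 0.0) and np.all(np.isfinite(pmdf.values))
    L = region_pathlengths(pmdf, sphere40_mesh)
    assert sum(L.L_norm.values()) == pytest.approx(1.0, abs=1e-12)
    assert all(0.0 <= v <= 1.0 for v in L.L_norm.values())
    # additivity: merging two parcels adds their normalized pathlengths
    ids = sorted(L.L_norm, key=L.L_norm.get)[-2:]
    merged_mesh_region = sphere40_mesh.node_region.copy()
    merged_mesh_region[merged_mesh_region == ids[1]] = ids[0]

    class _M:
        node_region = merged_mesh_region

    L2 = region_pathlengths(pmdf, _M)
    assert L2.L_norm[ids[0]] == pytest.approx(L.L_norm[ids[0]] + L.L_norm[ids[1]], abs=1e-12)


def test_pmdf_reciprocity_under_exchange(sphere40, sphere40_system):
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "C3", "vertical", 15.0)
    swapped = type(pair)(
        fiducial_label=pair.fiducial_label,
        orientation=pair.orientation,
        nominal_distance=pair.nominal_distance,
        source_position=pair.detector_position,
        detector_position=pair.source_position,
    )
    a = compute_pmdf(sphere40_system, pair)
    b = compute_pmdf(sphere40_system, swapped)
    assert a.base_intensity == pytest.approx(b.base_intensity, rel=1e-9)
    assert np.allclose(a.values, b.values, rtol=1e-9, atol=0.0)


def test_single_region_parcellation_gives_unit_lnorm(sphere40_system, sphere40, sphere40_mesh):
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "Cz", "circumferential", 15.0)
    pmdf = compute_pmdf(sphere40_system, pair)

    class _M:
        node_region = (sphere40_mesh.node_region > 0).astype(np.int32)

    L = region_pathlengths(pmdf, _M)
    assert L.N == 1 and L.L_norm[1] == pytest.approx(1.0, abs=1e-15)


def test_perturbing_region_outside_support(sphere40, sphere40_mesh, sphere40_system):
    """A parcel on the far side of the head carries ~zero pathlength."""
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "T4", "circumferential", 20.0)
    pmdf = compute_pmdf(sphere40_system, pair)
    L = region_pathlengths(pmdf, sphere40_mesh)
    far_region = min(L.l, key=L.l.get)
    labs = partial_pathlength_perturbation(sphere40_system, pair, far_region)
    assert labs < 1e-6


def test_unknown_region_raises(sphere40, sphere40_system):
    _, _, _, fids = sphere40
    pair = place_sd_pair(fids, "T4", "circumferential", 20.0)
    with pytest.raises(KeyError):
        partial_pathlength_perturbation(sphere40_system, pair, 10_000)


def test_whole_domain_pathlength_matches_finite_difference():
    """Perturbing everything recovers the total mean pathlength -dlnI/dmu_a."""
    from nirscc.forward import assemble_diffusion_system
    from nirscc.sensitivity import SDPair

    model = make_slab(40.0, 20.0, 2.0)
    mesh = voxel_to_tetmesh(model)
    props = OpticalProperties(tissues={TISSUE_LABELS["scalp"]: HOMOG})
    system = assemble_diffusion_system(mesh, props)
    zmin = mesh.nodes[:, 2].min()
    pair = SDPair(
        fiducial_label="",
        orientation="circumferential",
        nominal_distance=15.0,
        source_position=np.array([-7.5, 0.0, zmin]),
        detector_position=np.array([7.5, 0.0, zmin]),
    )
    everywhere = np.ones(mesh.n_nodes, bool)
    labs = _perturbed_pathlength(system, pair, everywhere, 1e-3 * HOMOG.mu_a)

    # central-difference oracle at a smaller step (kappa held fixed, as in the
    # forward model's absorption-perturbation convention)
    from nirscc.sensitivity import _optode_fields

    _, _, i_base = _optode_fields(system, pair)
    d = 1e-4 * HOMOG.mu_a
    i_plus = _intensity_with_bump(system, pair, everywhere, +d)
    i_minus = _intensity_with_bump(system, pair, everywhere, -d)
    oracle = (np.log(i_minus) - np.log(i_plus)) / (2 * d)
    assert labs == pytest.approx(oracle, rel=0.01)


def _intensity_with_bump(system, pair, mask, bump):
    dM = _region_increment_mass(system, mask, bump)
    s_nodes, s_w = system.optode_weights(pair.source_position)
    d_nodes, d_w = system.optode_weights(pair.detector_position)
    rhs = np.zeros(system.mesh.n_nodes)
    rhs[s_nodes] = s_w
    phi = system.solve_perturbed(dM, rhs)
    return float(d_w @ phi[d_nodes])
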