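"""Phantom geometry: shells, parcellation, landmarks and 10-10 fiducials."""

import numpy as np
import pytest

from nirscc.phantom import (
    FIDUCIAL_1010_LABELS,
    InvalidSpecError,
    PhantomSpec,
    TISSUE_LABELS,
    build_sphere_phantom,
    load_voxel_model_nifti,
    place_fiducials_1010,
    place_landmarks,
    save_voxel_model_nifti,
)

AIR = TISSUE_LABELS["air"]


@pytest.mark.parametrize(
    "kwargs",
    [
        dict(outer_radius=10.0),  # shells (10.7 mm) exceed the radius
        dict(scalp_thickness=-1.0),
        dict(csf_thickness=0.0),
        dict(n_regions_per_hemisphere=0),
        dict(voxel_size=0.0),
    ],
)
def test_invalid_specs_rejected(kwargs):
    with pytest.raises(InvalidSpecError):
        PhantomSpec(**kwargs)


def _radial_extent(model, tissue, direction):
    """[min, max] center-distance of voxels of one tissue along a ray."""
    c = -model.origin / model.voxel_size  # center voxel index
    ts = np.arange(0.0, model.labels.shape[0] * model.voxel_size, 0.1)
    idx = np.round(c + np.outer(ts, direction) / model.voxel_size).astype(int)
    ok = np.all((idx >= 0) & (idx < np.array(model.shape)), axis=1)
    lab = model.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
    t = ts[ok][lab == tissue]
    return (t.min(), t.max()) if len(t) else (np.nan, np.nan)


@pytest.mark.parametrize("age,scalp,skull", [("0yo", 3.5, 2.2), ("1yo", 4.0, 3.0), ("2yo", 4.0, 3.8)])
def test_age_layer_thicknesses_by_ray_casting(age, scalp, skull):
    """Scalp and skull shell thicknesses match the age presets within a voxel."""
    spec = PhantomSpec.for_age(age, voxel_size=1.0)
    model = build_sphere_phantom(spec)
    rng = np.random.default_rng(0)
    for _ in range(5):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        lo_s, hi_s = _radial_extent(model, TISSUE_LABELS["scalp"], u)
        lo_k, hi_k = _radial_extent(model, TISSUE_LABELS["skull"], u)
        assert hi_s - lo_s == pytest.approx(scalp, abs=1.5 * spec.voxel_size)
        assert hi_k - lo_k == pytest.approx(skull, abs=1.5 * spec.voxel_size)
        assert lo_s > hi_k  # scalp strictly outside skull


def test_shell_nesting_ray_order():
    """Radial label sequence is always a subsequence of WM-GM-CSF-skull-scalp-air."""
    model = build_sphere_phantom(PhantomSpec(outer_radius=30.0, voxel_size=1.0))
    rng = np.random.default_rng(1)
    expected = [5, 4, 3, 2, 1, 0]
    for _ in range(20):
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        c = -model.origin / model.voxel_size
        ts = np.arange(0.0, 35.0, 0.05)
        idx = np.round(c + np.outer(ts, u)).astype(int)
        ok = np.all((idx >= 0) & (idx < np.array(model.shape)), axis=1)
        lab = model.labels[idx[ok, 0], idx[ok, 1], idx[ok, 2]]
        dedup = [int(x) for i, x in enumerate(lab) if i == 0 or x != lab[i - 1]]
        it = iter(expected)
        assert all(any(x == y for y in it) for x in dedup), dedup


def test_gm_voxel_count_matches_shell_volume():
    """GM voxel count agrees with the analytic spherical-shell volume within 5%."""
    spec = PhantomSpec(outer_radius=60.0, voxel_size=1.0)
    model = build_sphere_phantom(spec)
    r_out = 60.0 - 3.5 - 2.2 - 2.0
    r_in = r_out - 3.0
    analytic = 4.0 / 3.0 * np.pi * (r_out**3 - r_in**3)
    count = int((model.labels == TISSUE_LABELS["gm"]).sum())
    assert count * spec.voxel_size**3 == pytest.approx(analytic, rel=0.05)


def test_region_partition_and_determinism():
    spec = PhantomSpec(outer_radius=30.0, voxel_size=2.0, n_regions_per_hemisphere=7)
    a = build_sphere_phantom(spec)
    b = build_sphere_phantom(spec)
    assert np.array_equal(a.labels, b.labels) and np.array_equal(a.regions, b.regions)
    brain = (a.labels == TISSUE_LABELS["gm"]) | (a.labels == TISSUE_LABELS["wm"])
    assert np.all((a.regions > 0) == brain)
    assert a.regions.max() <= 14


def test_single_region_parcellation():
    spec = PhantomSpec(outer_radius=25.0, voxel_size=2.0, n_regions_per_hemisphere=1)
    model = build_sphere_phantom(spec)
    used = set(np.unique(model.regions)) - {0}
    assert used == {1, 2}  # one region per hemisphere


def test_landmarks_on_surface_at_compass_points(sphere40):
    spec, model, lm, _ = sphere40
    R = spec.outer_radius
    for p, direction in [
        (lm.nasion, [0, 1, 0]),
        (lm.inion, [0, -1, 0]),
        (lm.right_periauricular, [1, 0, 0]),
        (lm.left_periauricular, [-1, 0, 0]),
    ]:
        assert np.linalg.norm(p) == pytest.approx(R, abs=spec.voxel_size)
        assert np.dot(p / np.linalg.norm(p), direction) > 0.999


def test_nasion_inion_geodesic_half_circumference(sphere40):
    """The surface arc nasion -> inion equals pi * R within 1%."""
    spec, model, lm, fids = sphere40
    # chord-sum along the sagittal fiducial line nasion -> Fpz .. Oz -> inion
    line = [lm.nasion] + [fids[k] for k in ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]] + [lm.inion]
    chord = sum(np.linalg.norm(b - a) for a, b in zip(line, line[1:]))
    # correct polyline -> arc: chord c of angle t has arc t = 2 asin(c/2R)
    assert chord == pytest.approx(np.pi * spec.outer_radius, rel=0.01)


def test_fiducials_complete_on_surface_and_symmetric(sphere40):
    spec, model, _, fids = sphere40
    assert len(fids) == 61 and set(fids.points) == set(FIDUCIAL_1010_LABELS)
    for p in fids.points.values():
        assert np.linalg.norm(p) == pytest.approx(spec.outer_radius, abs=spec.voxel_size)
    # Cz at the top pole
    cz = fids["Cz"]
    assert cz[2] == pytest.approx(fids.radius, abs=1e-6)
    # left/right mirror pairs reflect through the sagittal (x=0) plane
    pairs = [("T3", "T4"), ("C3", "C4"), ("F7", "F8"), ("O1", "O2"),
             ("AF3", "AF4"), ("FC5", "FC6"), ("P5", "P6"), ("TP7", "TP8")]
    for left, right in pairs:
        mirrored = fids[right] * np.array([-1.0, 1.0, 1.0])
        assert np.allclose(fids[left], mirrored, atol=spec.voxel_size / 2)


def test_nifti_round_trip(tmp_path):
    model = build_sphere_phantom(PhantomSpec(outer_radius=20.0, voxel_size=2.0))
    lp, rp = tmp_path / "labels.nii.gz", tmp_path / "regions.nii.gz"
    save_voxel_model_nifti(model, lp, rp)
    back = load_voxel_model_nifti(lp, rp)
    assert np.array_equal(back.labels, model.labels)
    assert np.array_equal(back.regions, model.regions)
    assert back.voxel_size == model.voxel_size
    assert np.allclose(back.origin, model.origin)
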