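"""Synthetic five-layer head phantoms with a cortical parcellation and 10-10 fiducials.

The phantom is a concentric-shell sphere (scalp / skull / CSF / GM / WM from the
outside in) on a regular voxel grid, with the brain (GM+WM) partitioned into
angular-sector parcels split by hemisphere.  A sphere is used deliberately: every
downstream quantity (mesh volume, geodesic lengths, fiducial symmetry) then has a
closed-form oracle, while all channel-level metrics are geometry-agnostic.

Coordinates are millimetres, voxel-center based, right-handed RAS:
+x right, +y anterior, +z superior.  The grid is 0-based.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUE_LABELS",
    "TISSUE_NAMES",
    "PhantomSpec",
    "VoxelModel",
    "Landmarks",
    "FiducialSet",
    "FIDUCIAL_1010_LABELS",
    "build_sphere_phantom",
    "place_landmarks",
    "place_fiducials_1010",
    "save_voxel_model_nifti",
    "load_voxel_model_nifti",
    "InvalidSpecError",
    "EmptyModelError",
]

#: integer labels of the six material classes of the voxel image
TISSUE_LABELS = {"air": 0, "scalp": 1, "skull": 2, "csf": 3, "gm": 4, "wm": 5}
TISSUE_NAMES = {v: k for k, v in TISSUE_LABELS.items()}

#: age presets: outer radius from typical head circumference (35 / 46 / 48.5 cm),
#: scalp and skull thicknesses for 0-, 1-, 2-year-olds
_AGE_PRESETS = {
    "0yo": dict(outer_radius=56.0, scalp_thickness=3.5, skull_thickness=2.2),
    "1yo": dict(outer_radius=73.0, scalp_thickness=4.0, skull_thickness=3.0),
    "2yo": dict(outer_radius=77.0, scalp_thickness=4.0, skull_thickness=3.8),
}


class InvalidSpecError(ValueError):
    """Phantom specification violates its invariants."""


class EmptyModelError(ValueError):
    """Voxel model contains no non-air voxels / no scalp surface."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a spherical five-layer head phantom.

    All lengths in mm.  ``n_regions_per_hemisphere`` emulates a macro-anatomical
    parcellation (45 per hemisphere echoes the 90-region AAL atlas).
    """

    outer_radius: float = 56.0
    scalp_thickness: float = 3.5
    skull_thickness: float = 2.2
    csf_thickness: float = 2.0
    gm_thickness: float = 3.0
    voxel_size: float = 1.0
    n_regions_per_hemisphere: int = 45
    age_label: str = "custom"
    seed: int = 0

    def __post_init__(self) -> None:
        th = (
            self.scalp_thickness,
            self.skull_thickness,
            self.csf_thickness,
            self.gm_thickness,
        )
        if any(t <= 0 for t in th):
            raise InvalidSpecError("all shell thicknesses must be > 0")
        if sum(th) >= self.outer_radius:
            raise InvalidSpecError(
                f"shell thicknesses sum to {sum(th):g} mm, "
                f"must be < outer radius {self.outer_radius:g} mm"
            )
        if self.voxel_size <= 0:
            raise InvalidSpecError("voxel_size must be > 0")
        if self.n_regions_per_hemisphere < 1:
            raise InvalidSpecError("n_regions_per_hemisphere must be >= 1")

    @classmethod
    def for_age(cls, age_label: str, **overrides) -> "PhantomSpec":
        """Preset for ``'0yo'``, ``'1yo'`` or ``'2yo'``.

        Scalp/skull thicknesses are the age-representative values used for
        infant head modelling (3.5/4/4 mm scalp and 2.2/3/3.8 mm skull).
        """
        if age_label not in _AGE_PRESETS:
            raise InvalidSpecError(f"unknown age label {age_label!r}")
        kw = dict(_AGE_PRESETS[age_label])
        kw["age_label"] = age_label
        kw.update(overrides)
        return cls(**kw)


@dataclass
class VoxelModel:
    """Labelled voxel image plus brain parcellation.

    ``labels``: int8 grid with values of :data:`TISSUE_LABELS`.
    ``regions``: int32 grid, 0 outside the brain, 1..N parcel ids on GM/WM voxels.
    ``origin``: mm coordinate of the center of voxel (0, 0, 0).
    """

    labels: np.ndarray
    regions: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.regions = np.asarray(self.regions)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.shape != self.regions.shape:
            raise ValueError("labels and regions must have the same shape")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def voxel_center(self, idx: np.ndarray) -> np.ndarray:
        """mm coordinate(s) of voxel index/indices."""
        return self.origin + np.asarray(idx, dtype=float) * self.voxel_size

    def n_regions(self) -> int:
        return int(self.regions.max(initial=0))


@dataclass(frozen=True)
class Landmarks:
    """The four anatomical landmarks on the scalp surface (mm)."""

    nasion: np.ndarray
    inion: np.ndarray
    left_periauricular: np.ndarray
    right_periauricular: np.ndarray


@dataclass
class FiducialSet:
    """10-10 fiducial points on the scalp plus the fitted surface frame.

    ``points`` maps the 61 standard labels to mm coordinates.  ``center``,
    ``radius`` and the frame axes describe the sphere the points live on and are
    used downstream to walk geodesics when placing source-detector pairs.
    """

    points: dict
    center: np.ndarray
    radius: float
    axis_right: np.ndarray
    axis_anterior: np.ndarray
    axis_superior: np.ndarray

    def __getitem__(self, label: str) -> np.ndarray:
        return self.points[label]

    def __len__(self) -> int:
        return len(self.points)

    def __contains__(self, label: str) -> bool:
        return label in self.points


# --------------------------------------------------------------------------- #
# phantom construction
# --------------------------------------------------------------------------- #


def build_sphere_phantom(spec: PhantomSpec) -> VoxelModel:
    """Voxelize a concentric five-shell sphere and parcellate its brain.

    Shells are assigned by the distance of each voxel center from the sphere
    center, which makes the radial label order WM -> GM -> CSF -> skull ->
    scalp -> air exact by construction.  Parcels are angular sectors: equal
    bands of z-direction cosine, subdivided in azimuth, split left/right by the
    sign of x.  The construction is fully deterministic (the seed is recorded
    for provenance only).
    """
    h = spec.voxel_size
    R = spec.outer_radius
    n_half = int(np.ceil(R / h)) + 2
    n = 2 * n_half + 1  # odd grid; sphere center on a voxel center
    origin = -np.full(3, n_half * h)

    ax = (np.arange(n) - n_half) * h
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    d = np.sqrt(x * x + y * y + z * z)

    r_scalp = R
    r_skull = R - spec.scalp_thickness
    r_csf = r_skull - spec.skull_thickness
    r_gm = r_csf - spec.csf_thickness
    r_wm = r_gm - spec.gm_thickness

    labels = np.zeros((n, n, n), dtype=np.int8)
    labels[d <= r_scalp] = TISSUE_LABELS["scalp"]
    labels[d <= r_skull] = TISSUE_LABELS["skull"]
    labels[d <= r_csf] = TISSUE_LABELS["csf"]
    labels[d <= r_gm] = TISSUE_LABELS["gm"]
    labels[d <= r_wm] = TISSUE_LABELS["wm"]

    regions = np.zeros((n, n, n), dtype=np.int32)
    brain = (labels == TISSUE_LABELS["gm"]) | (labels == TISSUE_LABELS["wm"])
    if brain.any():
        ub = np.stack([x[brain], y[brain], z[brain]], axis=1)
        norm = np.linalg.norm(ub, axis=1)
        norm[norm == 0] = 1.0
        u = ub / norm[:, None]
        sector = _angular_sector(u, spec.n_regions_per_hemisphere)
        # left hemisphere (x < 0): ids 1..k ; right: k+1..2k
        k = spec.n_regions_per_hemisphere
        rid = np.where(ub[:, 0] < 0, sector + 1, sector + 1 + k)
        regions[brain] = rid

    return VoxelModel(labels=labels, regions=regions, voxel_size=h, origin=origin)


def _angular_sector(u: np.ndarray, k: int) -> np.ndarray:
    """Sector index 0..k-1 for unit directions ``u`` within one hemisphere.

    Bands are equal intervals of u_z; each band is split in the angle
    atan2(u_y, u_z) so parcel boundaries run roughly anterior-posterior.
    """
    if k == 1:
        return np.zeros(len(u), dtype=np.int64)
    n_band = max(1, int(round(np.sqrt(k / 2.0))))
    base, rem = divmod(k, n_band)
    counts = [base + 1 if b < rem else base for b in range(n_band)]
    offsets = np.concatenate([[0], np.cumsum(counts)])

    band = np.clip(((u[:, 2] + 1.0) / 2.0 * n_band).astype(np.int64), 0, n_band - 1)
    ang = np.arctan2(u[:, 1], u[:, 2])  # (-pi, pi]
    frac = (ang + np.pi) / (2 * np.pi)
    nb = np.asarray(counts)[band]
    slot = np.clip((frac * nb).astype(np.int64), 0, nb - 1)
    return offsets[band] + slot


# --------------------------------------------------------------------------- #
# surface fit, landmarks, 10-10 fiducials
# --------------------------------------------------------------------------- #


def _fit_scalp_sphere(model: VoxelModel) -> tuple:
    """Estimate (center, radius) of the outer scalp surface from the voxel image.

    Surface voxels are non-air voxels with at least one 6-neighbour that is air
    (or that lie on the grid boundary).  The radius adds half a voxel because
    the physical boundary sits between the last tissue voxel center and its air
    neighbour.
    """
    nonair = model.labels != TISSUE_LABELS["air"]
    if not nonair.any():
        raise EmptyModelError("model contains no tissue voxels")
    surf = _surface_mask(nonair)
    idx = np.argwhere(surf)
    pts = model.voxel_center(idx)
    center = pts.mean(axis=0)
    radius = float(np.linalg.norm(pts - center, axis=1).mean()) + model.voxel_size / 2.0
    return center, radius


def _surface_mask(nonair: np.ndarray) -> np.ndarray:
    interior = np.ones_like(nonair)
    for axis in range(3):
        for shift in (1, -1):
            interior &= np.roll(nonair, shift, axis=axis)
        # grid-edge voxels count as surface
        sl = [slice(None)] * 3
        sl[axis] = 0
        interior[tuple(sl)] = False
        sl[axis] = -1
        interior[tuple(sl)] = False
    return nonair & ~interior


def place_landmarks(model: VoxelModel) -> Landmarks:
    """Locate nasion, inion and the two periauricular points on the scalp.

    The scalp surface is fit as a sphere; the landmarks are the intersections of
    the fitted surface with the +y/-y (anterior/posterior) and +x/-x (lateral)
    axes through its center, i.e. the four equatorial compass points of the
    axial mid-plane.
    """
    center, radius = _fit_scalp_sphere(model)
    ex = np.array([1.0, 0.0, 0.0])
    ey = np.array([0.0, 1.0, 0.0])
    return Landmarks(
        nasion=center + radius * ey,
        inion=center - radius * ey,
        left_periauricular=center - radius * ex,
        right_periauricular=center + radius * ex,
    )


def _circle_through(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Center, radius and in-plane basis of the unique circle through 3 points."""
    v1 = p2 - p1
    v2 = p3 - p1
    n = np.cross(v1, v2)
    nn = np.dot(n, n)
    if nn < 1e-12:
        raise ValueError("collinear points have no finite circumcircle")
    # circumcenter (standard closed form)
    c = p1 + (
        np.cross(np.dot(v1, v1) * v2 - np.dot(v2, v2) * v1, np.cross(v1, v2))
    ) / (2 * nn)
    r = float(np.linalg.norm(p1 - c))
    e1 = (p1 - c) / r
    ez = n / np.sqrt(nn)
    e2 = np.cross(ez, e1)
    return c, r, e1, e2


def _arc_points(p_left, p_mid, p_right, n_half: int) -> list:
    """Equal-angle subdivision of the circular arc left -> mid -> right.

    Returns the 2*n_half - 1 interior points excluding the three inputs'
    endpoints, i.e. [left..(n_half-1 pts)..mid..(n_half-1 pts)..right] with
    endpoints and midpoint dropped by the caller as needed; here we return the
    full sampled list including endpoints for simplicity.
    """
    c, r, e1, e2 = _circle_through(p_left, p_mid, p_right)

    def ang(p):
        v = p - c
        return np.arctan2(np.dot(v, e2), np.dot(v, e1))

    a_l = 0.0
    a_m = ang(p_mid) % (2 * np.pi)
    a_r = ang(p_right) % (2 * np.pi)
    # walk in the direction that reaches mid before right
    if a_m > a_r:
        a_m -= 2 * np.pi
        a_r -= 2 * np.pi
    angs = np.concatenate(
        [np.linspace(a_l, a_m, n_half + 1), np.linspace(a_m, a_r, n_half + 1)[1:]]
    )
    return [c + r * (np.cos(a) * e1 + np.sin(a) * e2) for a in angs]


#: the 61 labels of the 10-10 fiducial system used here
FIDUCIAL_1010_LABELS = (
    "Fpz AFz Fz FCz Cz CPz Pz POz Oz "
    "Fp1 AF7 F7 FT7 T3 TP7 T5 PO7 O1 "
    "Fp2 AF8 F8 FT8 T4 TP8 T6 PO8 O2 "
    "C5 C3 C1 C2 C4 C6 "
    "AF3 AF4 F5 F3 F1 F2 F4 F6 "
    "FC5 FC3 FC1 FC2 FC4 FC6 "
    "CP5 CP3 CP1 CP2 CP4 CP6 "
    "P5 P3 P1 P2 P4 P6 PO3 PO4"
).split()


def place_fiducials_1010(model: VoxelModel, lm: Landmarks) -> FiducialSet:
    """Construct the 61 fiducial points of the international 10-10 system.

    Standard construction: the nasion-inion and periauricular geodesics are
    subdivided at 10% increments (their crossing is Cz), the circumferential
    ring through Fpz/T3/Oz/T4 likewise, and the intermediate coronal arcs are
    subdivided through their midline points.  On the spherical phantom all arcs
    are exact circle sections of the fitted scalp sphere.
    """
    center, radius = _fit_scalp_sphere(model)

    ant = _unit(lm.nasion - center)
    right = _unit(lm.right_periauricular - center)
    # orthonormalize; superior completes the right-handed frame
    right = _unit(right - np.dot(right, ant) * ant)
    sup = np.cross(right, ant)

    def on_sphere(u):
        return center + radius * _unit(u)

    pts: dict = {}

    # sagittal arc nasion -> inion through Cz, 10% steps
    sag = ["Fpz", "AFz", "Fz", "FCz", "Cz", "CPz", "Pz", "POz", "Oz"]
    for i, name in enumerate(sag, start=1):
        a = np.pi * i / 10.0
        pts[name] = on_sphere(np.cos(a) * ant + np.sin(a) * sup)

    # coronal arc LPA -> RPA through Cz (T3 at 10%, ... T4 at 90%)
    cor = ["T3", "C5", "C3", "C1", None, "C2", "C4", "C6", "T4"]
    for i, name in enumerate(cor, start=1):
        if name is None:
            continue  # Cz already placed
        a = np.pi * i / 10.0
        pts[name] = on_sphere(-np.cos(a) * right + np.sin(a) * sup)

    # circumferential ring through Fpz, T3, Oz, T4 at elevation 18 deg,
    # 10% steps of each half ring (negative psi = left)
    elev = np.pi * 0.1
    ring_left = ["Fp1", "AF7", "F7", "FT7", None, "TP7", "T5", "PO7", "O1"]
    ring_right = ["Fp2", "AF8", "F8", "FT8", None, "TP8", "T6", "PO8", "O2"]
    for i in range(1, 10):
        psi = np.pi * i / 10.0
        u_l = np.cos(elev) * (np.cos(psi) * ant - np.sin(psi) * right) + np.sin(elev) * sup
        u_r = np.cos(elev) * (np.cos(psi) * ant + np.sin(psi) * right) + np.sin(elev) * sup
        if ring_left[i - 1] is not None:
            pts[ring_left[i - 1]] = on_sphere(u_l)
        if ring_right[i - 1] is not None:
            pts[ring_right[i - 1]] = on_sphere(u_r)

    # intermediate coronal rows: arc from left ring point through the midline
    # point to the right ring point, halves subdivided in quarters (or halves)
    rows = [
        ("AF7", "AFz", "AF8", 2, ["AF3"], ["AF4"]),
        ("F7", "Fz", "F8", 4, ["F5", "F3", "F1"], ["F2", "F4", "F6"]),
        ("FT7", "FCz", "FT8", 4, ["FC5", "FC3", "FC1"], ["FC2", "FC4", "FC6"]),
        ("TP7", "CPz", "TP8", 4, ["CP5", "CP3", "CP1"], ["CP2", "CP4", "CP6"]),
        ("T5", "Pz", "T6", 4, ["P5", "P3", "P1"], ["P2", "P4", "P6"]),
        ("PO7", "POz", "PO8", 2, ["PO3"], ["PO4"]),
    ]
    for left, mid, rgt, nseg, lnames, rnames in rows:
        arc = _arc_points(pts[left], pts[mid], pts[rgt], nseg)
        # arc = [left, ...interior..., mid, ...interior..., right]
        for j, name in enumerate(lnames, start=1):
            pts[name] = arc[j]
        for j, name in enumerate(rnames, start=1):
            pts[name] = arc[nseg + j]

    assert set(pts) == set(FIDUCIAL_1010_LABELS) and len(pts) == 61
    return FiducialSet(
        points=pts,
        center=center,
        radius=radius,
        axis_right=right,
        axis_anterior=ant,
        axis_superior=sup,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


# --------------------------------------------------------------------------- #
# NIfTI round trip (so real segmented label volumes can be substituted)
# --------------------------------------------------------------------------- #


def save_voxel_model_nifti(model: VoxelModel, labels_path, regions_path) -> None:
    """Write labels and regions as two NIfTI-1 images with a mm affine."""
    import nibabel as nib

    affine = np.diag([model.voxel_size] * 3 + [1.0])
    affine[:3, 3] = model.origin
    nib.save(nib.Nifti1Image(model.labels.astype(np.int16), affine), str(labels_path))
    nib.save(nib.Nifti1Image(model.regions.astype(np.int32), affine), str(regions_path))


def load_voxel_model_nifti(labels_path, regions_path) -> VoxelModel:
    """Read a labels/regions NIfTI pair written by :func:`save_voxel_model_nifti`.

    Accepts any pair of co-registered label images with an isotropic diagonal
    affine, so real segmented head volumes can stand in for the phantom.
    """
    import nibabel as nib

    li = nib.load(str(labels_path))
    ri = nib.load(str(regions_path))
    zooms = li.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0]):
        raise ValueError("only isotropic voxel label images are supported")
    labels = np.asarray(li.dataobj).astype(np.int8)
    regions = np.asarray(ri.dataobj).astype(np.int32)
    origin = np.asarray(li.affine[:3, 3], dtype=float)
    return VoxelModel(labels=labels, regions=regions, voxel_size=float(zooms[0]), origin=origin)
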