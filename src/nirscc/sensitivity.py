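"""Channel sensitivity: PMDF fields, regional partial pathlengths, perturbation.

The photon measurement density function (PMDF, also called the spatial
sensitivity profile) of a source-detector pair is the sensitivity of the
log-detected intensity to a local absorption change,

    PMDF(r) = Phi_src(r) Phi_det(r) / I_base ,

computed here in its discrete adjoint form: the derivative of ln I with
respect to each *nodal* absorption coefficient,

    PMDF_n = Phi_src(n) Phi_det(n) V_n / I_base   [mm],

with V_n the lumped nodal volume, which is exactly
(1/I_base) Phi_det^T (dA/dmu_a,n) Phi_src for the lumped-mass absorption term
of the assembled operator A.  Summing PMDF over the nodes of a brain parcel
gives the partial pathlength (PPL) of that parcel; it agrees with the direct
absorption-perturbation estimate to first order *by construction*, which the
test-suite uses as a two-route cross-check.

Normalized PPLs

    Lnorm_M = l_M / sum_j l_j      (sum over brain parcels only)

form a probability simplex over parcels and are the basis of all channel
metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .forward import DiffusionSystem, SourceSpec, solve_fluence
from .phantom import FiducialSet

__all__ = [
    "SDPair",
    "PMDFField",
    "RegionPathlengths",
    "place_sd_pair",
    "compute_pmdf",
    "region_pathlengths",
    "partial_pathlength_perturbation",
    "DegenerateMeasurementError",
]

SD_DISTANCES_MM = (10.0, 15.0, 20.0, 25.0, 30.0)
ORIENTATIONS = ("circumferential", "vertical")


class DegenerateMeasurementError(RuntimeError):
    """Detected baseline intensity is zero / all-zero brain sensitivity."""


@dataclass(frozen=True)
class SDPair:
    """A source-detector pair centred on a 10-10 fiducial point."""

    fiducial_label: str
    orientation: str
    nominal_distance: float
    source_position: np.ndarray
    detector_position: np.ndarray


def place_sd_pair(
    fiducials: FiducialSet,
    label: str,
    orientation: str,
    distance: float,
) -> SDPair:
    """Place source and detector at +-distance/2 geodesically from a fiducial.

    The circumferential direction is the tangent of the horizontal ring through
    the fiducial (the T3-T4 ring direction); the vertical direction is the
    surface tangent toward Cz.  At Cz itself these degenerate and the
    circumferential/vertical pairs are laid along the coronal (toward the right
    periauricular) and sagittal (toward the nasion) great circles respectively.
    Both endpoints lie on the scalp sphere at exactly the nominal geodesic
    distance.
    """
    if label not in fiducials:
        raise KeyError(f"unknown fiducial label {label!r}")
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    c, r = fiducials.center, fiducials.radius
    u = (fiducials[label] - c) / r
    zhat = fiducials.axis_superior

    horiz = np.cross(zhat, u)
    nh = np.linalg.norm(horiz)
    if nh > 1e-8:
        t_circ = horiz / nh
        t_vert_raw = zhat - np.dot(zhat, u) * u
        t_vert = t_vert_raw / np.linalg.norm(t_vert_raw)
    else:  # at Cz: coronal / sagittal fallback
        t_circ = fiducials.axis_right
        t_vert = fiducials.axis_anterior
    t = t_circ if orientation == "circumferential" else t_vert

    alpha = (distance / 2.0) / r
    src = c + r * (np.cos(alpha) * u + np.sin(alpha) * t)
    det = c + r * (np.cos(alpha) * u - np.sin(alpha) * t)
    return SDPair(
        fiducial_label=label,
        orientation=orientation,
        nominal_distance=float(distance),
        source_position=src,
        detector_position=det,
    )


@dataclass
class PMDFField:
    """Per-node PMDF of one SD pair (pathlength units, mm)."""

    values: np.ndarray
    pair: SDPair
    base_intensity: float

    def support_size(self, rel_threshold: float = 0.01) -> int:
        """Number of nodes with PMDF above rel_threshold * max."""
        return int(np.count_nonzero(self.values > rel_threshold * self.values.max()))


def _optode_fields(system: DiffusionSystem, pair: SDPair):
    """Source and adjoint (detector) fields plus the detected baseline intensity."""
    phi_s = system.solve_optode(pair.source_position)
    phi_d = system.solve_optode(pair.detector_position)
    d_nodes, d_w = system.optode_weights(pair.detector_position)
    i_base = float(d_w @ phi_s[d_nodes])
    return phi_s, phi_d, i_base


def compute_pmdf(system: DiffusionSystem, pair: SDPair) -> PMDFField:
    """Adjoint PMDF: sensitivity of ln(I) to the absorption at every node.

    The detector field is the solve with the detector's optode load as source
    (adjoint of the detection functional); the product with the source field,
    weighted by the lumped nodal volume and divided by the detected baseline
    intensity (the Rytov form), puts the field in pathlength units so that
    parcel sums are partial pathlengths.
    """
    phi_s, phi_d, i_base = _optode_fields(system, pair)
    if not np.isfinite(i_base) or i_base <= 0:
        raise DegenerateMeasurementError("detected baseline intensity is not positive")
    values = phi_s * phi_d * system.mesh.nodal_volumes() / i_base
    return PMDFField(values=values, pair=pair, base_intensity=i_base)


@dataclass
class RegionPathlengths:
    """Partial pathlengths per brain parcel and their normalized form."""

    l: dict  # region id -> l_M [mm]
    L_norm: dict  # region id -> Lnorm_M
    N: int  # number of brain parcels with nodes in the mesh

    def as_arrays(self):
        ids = np.array(sorted(self.l))
        return ids, np.array([self.l[i] for i in ids]), np.array([self.L_norm[i] for i in ids])


def region_pathlengths(pmdf: PMDFField, mesh) -> RegionPathlengths:
    """Sum the PMDF over each brain parcel and normalize over parcels.

    Non-brain nodes (region 0) are excluded from the denominator, so the
    normalized values express the share of *brain* pathlength per parcel and
    sum to 1 exactly.
    """
    reg = mesh.node_region
    brain = reg > 0
    if not brain.any():
        raise DegenerateMeasurementError("mesh has no brain-labelled nodes")
    sums = np.bincount(reg[brain], weights=pmdf.values[brain])
    ids = np.nonzero(np.bincount(reg[brain]))[0]
    total = float(sums[ids].sum())
    if total <= 0:
        raise DegenerateMeasurementError("PMDF carries no brain sensitivity")
    l = {int(i): float(sums[i]) for i in ids}
    L_norm = {int(i): float(sums[i] / total) for i in ids}
    return RegionPathlengths(l=l, L_norm=L_norm, N=len(ids))


def _region_increment_mass(system: DiffusionSystem, node_mask: np.ndarray, bump: float):
    """Lumped mass matrix of the field that is ``bump`` on masked nodes, 0 elsewhere."""
    from .forward import _absorption_mass

    mu = np.where(node_mask, float(bump), 0.0)
    vol = system.mesh.element_volumes()
    return _absorption_mass(system.mesh.elements, vol, mu)


def partial_pathlength_perturbation(
    system: DiffusionSystem,
    pair: SDPair,
    region: int,
    delta_frac: float = 0.001,
) -> float:
    """Direct (perturbation) estimate of the partial pathlength of one parcel.

    The nodal absorption over the parcel is raised by a uniform increment of
    ``delta_frac`` (default 0.1%) of the parcel's mean absorption coefficient,
    the system re-solved, and

        L_abs = ln(I_base / I_pert) / delta      [mm]

    returned, the CW pathlength estimator.  For a tissue-homogeneous parcel
    this is identical to multiplying the parcel's mu_a by (1 + delta_frac) and
    dividing by delta_frac * mu_a.
    """
    mask = system.mesh.node_region == int(region)
    if not mask.any():
        raise KeyError(f"region {region} has no nodes in the mesh")
    mu_ref = float(system.node_mu_a[mask].mean())
    bump = delta_frac * mu_ref
    return _perturbed_pathlength(system, pair, mask, bump)


def _perturbed_pathlength(system, pair, node_mask, bump) -> float:
    """ln(I_base/I_pert)/bump for an additive absorption bump on masked nodes."""
    phi_s, _, i_base = _optode_fields(system, pair)
    if i_base <= 0:
        raise DegenerateMeasurementError("detected baseline intensity is not positive")
    dM = _region_increment_mass(system, node_mask, bump)
    s_nodes, s_w = system.optode_weights(pair.source_position)
    d_nodes, d_w = system.optode_weights(pair.detector_position)
    rhs = np.zeros(system.mesh.n_nodes)
    rhs[s_nodes] = s_w
    phi_pert = system.solve_perturbed(dM, rhs, x0=phi_s)
    i_pert = float(d_w @ phi_pert[d_nodes])
    if i_pert > i_base * (1.0 + 1e-12):
        raise RuntimeError(
            "perturbed intensity exceeds baseline: absorption increase must attenuate"
        )
    return float(np.log(i_base / i_pert) / bump)
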