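"""Continuous-wave diffusion-approximation forward solver on tetrahedral meshes.

The CW diffusion equation

    -div( kappa grad Phi ) + mu_a Phi = q ,   kappa = 1 / (3 (mu_a + mu_s'))

is discretized with linear (P1) elements.  The air/tissue boundary carries the
Robin (partial-current) condition

    kappa dPhi/dnu + Phi / (2 A) = 0

with A the internal-reflection parameter obtained from the tissue refractive
index by the Groenhuis polynomial approximation of the Fresnel reflection
integrals:

    r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n ,   A = (1 + r_d)/(1 - r_d).

Sources and detectors are isotropic point terms placed one transport mean free
path (1/mu_s' of the local surface tissue) beneath their scalp positions,
distributed onto the containing element by barycentric interpolation; the
detected intensity is the fluence interpolated at the detector's sub-surface
point.  Using the same weights on both ends makes source-detector exchange an
exact symmetry of the discrete Green function.

The diffusion coefficient kappa is computed per element from the baseline
properties and held fixed under absorption perturbations (the standard CW
absorption-Jacobian convention).  The absorption term is assembled from a
nodal mu_a field with lumped (nodal-quadrature) mass, diag(mu_a,n * V_n):
lumping preserves the M-matrix property of the non-obtuse structured mesh
(discrete maximum principle, hence positive fluence) and makes the absorption
Jacobian diagonal, so adjoint sensitivities and direct perturbations are
discretely consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .meshing import TetMesh
from .phantom import TISSUE_LABELS

__all__ = [
    "TissueOptics",
    "OpticalProperties",
    "default_properties",
    "adult_gm_wm_properties",
    "SourceSpec",
    "FluenceField",
    "DiffusionSystem",
    "assemble_diffusion_system",
    "solve_fluence",
    "detected_intensity",
    "analytic_semi_infinite",
    "internal_reflection_parameter",
    "SolverError",
    "PlacementError",
]


class SolverError(RuntimeError):
    """Linear solve failed to reach the requested residual."""


class PlacementError(ValueError):
    """Requested optode position is not on the mesh surface."""


@dataclass(frozen=True)
class TissueOptics:
    """Optical coefficients of one tissue: mu_a, mu_s [1/mm], g, n."""

    mu_a: float
    mu_s: float
    g: float
    n: float

    def __post_init__(self):
        if self.mu_a <= 0 or self.mu_s <= 0:
            raise ValueError("mu_a and mu_s must be > 0")
        if not 0 <= self.g < 1:
            raise ValueError("anisotropy g must be in [0, 1)")
        if self.n < 1:
            raise ValueError("refractive index must be >= 1")

    @property
    def mu_s_prime(self) -> float:
        """Reduced scattering coefficient mu_s' = mu_s (1 - g) [1/mm]."""
        return self.mu_s * (1.0 - self.g)

    @property
    def kappa(self) -> float:
        """Diffusion coefficient kappa = 1 / (3 (mu_a + mu_s')) [mm]."""
        return 1.0 / (3.0 * (self.mu_a + self.mu_s_prime))

    @property
    def mu_eff(self) -> float:
        """Effective attenuation sqrt(3 mu_a (mu_a + mu_s')) [1/mm]."""
        return np.sqrt(3.0 * self.mu_a * (self.mu_a + self.mu_s_prime))


@dataclass(frozen=True)
class OpticalProperties:
    """Per-tissue optical properties at one wavelength, keyed by tissue id."""

    tissues: dict  # tissue id -> TissueOptics
    wavelength_nm: float = 800.0

    def __getitem__(self, tissue_id: int) -> TissueOptics:
        return self.tissues[int(tissue_id)]

    def with_tissue(self, tissue_id: int, optics: TissueOptics) -> "OpticalProperties":
        tissues = dict(self.tissues)
        tissues[int(tissue_id)] = optics
        return replace(self, tissues=tissues)


def default_properties() -> OpticalProperties:
    """Infant head-tissue optical properties at 800 nm.

    mu_a / mu_s in 1/mm; g = 0.9 and n = 1.4 for all tissues, so mu_s' is
    scalp 1.9, skull 1.6, CSF 0.032, GM 0.5, WM 1.0 (all 1/mm).
    """
    t = TISSUE_LABELS
    return OpticalProperties(
        tissues={
            t["scalp"]: TissueOptics(0.018, 19.0, 0.9, 1.4),
            t["skull"]: TissueOptics(0.016, 16.0, 0.9, 1.4),
            t["csf"]: TissueOptics(0.0041, 0.32, 0.9, 1.4),
            t["gm"]: TissueOptics(0.048, 5.0, 0.9, 1.4),
            t["wm"]: TissueOptics(0.037, 10.0, 0.9, 1.4),
        }
    )


def adult_gm_wm_properties() -> OpticalProperties:
    """Infant table with adult grey/white-matter coefficients substituted.

    Used to probe how strongly the channel metrics depend on the uncertain
    brain optical properties (adult cortex scatters more than infant cortex).
    """
    t = TISSUE_LABELS
    props = default_properties()
    props = props.with_tissue(t["gm"], TissueOptics(0.036, 22.0, 0.9, 1.4))
    props = props.with_tissue(t["wm"], TissueOptics(0.014, 91.0, 0.9, 1.4))
    return props


def internal_reflection_parameter(n: float) -> float:
    """Internal reflection parameter A(n) by the Groenhuis polynomial."""
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    return (1.0 + r_d) / (1.0 - r_d)


@dataclass(frozen=True)
class SourceSpec:
    """Isotropic source under a scalp surface position."""

    surface_position: np.ndarray
    amplitude: float = 1.0


@dataclass
class FluenceField:
    """Nodal fluence of one solve, with the source that produced it."""

    values: np.ndarray
    source: SourceSpec
    system: "DiffusionSystem"


@dataclass
class DiffusionSystem:
    """Assembled SPD operator plus the geometry needed for optode handling."""

    mesh: TetMesh
    props: OpticalProperties
    matrix: sp.csr_matrix
    node_mu_a: np.ndarray
    element_kappa: np.ndarray
    boundary_centroids: np.ndarray
    boundary_normals: np.ndarray
    surface_tolerance: float
    robin_diagonal: np.ndarray = None  # lumped Robin boundary term per node
    _factor: object = field(default=None, repr=False)
    _point_cache: dict = field(default_factory=dict, repr=False)
    direct_node_limit: int = 300_000
    cg_rtol: float = 1e-10

    def factor(self):
        """Direct factorization, reordered by geometric nested dissection.

        The mesh nodes live on a regular lattice, so a coordinate-based nested
        dissection gives a far better elimination ordering than the generic
        column orderings (several-fold lower fill on head-sized meshes).
        Meshes above ``direct_node_limit`` fall back to an incomplete-LU
        preconditioner used inside CG.
        """
        if self._factor is None:
            if self.mesh.n_nodes <= self.direct_node_limit:
                perm = _nested_dissection(self.mesh.nodes)
                mat = self.matrix[perm][:, perm].tocsc()
                lu = spla.splu(
                    mat,
                    permc_spec="NATURAL",
                    diag_pivot_thresh=0.0,
                    options=dict(SymmetricMode=True),
                )
                inv_perm = np.argsort(perm)
                self._factor = _PermutedFactor(lu, perm, inv_perm)
            else:
                ilu = spla.spilu(self.matrix.tocsc(), drop_tol=1e-5, fill_factor=20)
                self._factor = ilu
        return self._factor

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        fac = self.factor()
        if self.mesh.n_nodes <= self.direct_node_limit:
            x = fac.solve(rhs)
        else:
            pre = spla.LinearOperator(self.matrix.shape, fac.solve)
            x, info = spla.cg(self.matrix, rhs, rtol=self.cg_rtol, atol=0.0, M=pre)
            if info != 0:
                raise SolverError(f"CG did not converge (info={info})")
        res = np.linalg.norm(self.matrix @ x - rhs) / max(np.linalg.norm(rhs), 1e-300)
        if res > 1e-8:
            raise SolverError(f"relative residual {res:.2e} exceeds 1e-8")
        return x

    def solve_optode(self, position: np.ndarray, _cache_max: int = 64) -> np.ndarray:
        """Memoized solve for a unit optode load at a scalp position (bounded FIFO)."""
        key = tuple(np.round(np.asarray(position, dtype=float), 9))
        if key not in self._point_cache:
            nodes, weights = self.optode_weights(position)
            rhs = np.zeros(self.mesh.n_nodes)
            rhs[nodes] = weights
            if len(self._point_cache) >= _cache_max:
                self._point_cache.pop(next(iter(self._point_cache)))
            self._point_cache[key] = self.solve(rhs)
        return self._point_cache[key]

    def solve_perturbed(
        self, delta_matrix: sp.spmatrix, rhs: np.ndarray, x0: np.ndarray | None = None
    ) -> np.ndarray:
        """Solve (A + dA) x = rhs by CG preconditioned with the factored A.

        Intended for small absorption perturbations, where the baseline
        factorization is an excellent preconditioner (and the baseline solution
        a near-optimal initial guess), so CG converges in a few iterations at
        tight tolerance.
        """
        mat = (self.matrix + delta_matrix).tocsr()
        fac = self.factor()
        pre = spla.LinearOperator(mat.shape, fac.solve)
        x, info = spla.cg(mat, rhs, rtol=1e-12, atol=0.0, M=pre, x0=x0, maxiter=200)
        if info != 0:
            raise SolverError(f"perturbed CG did not converge (info={info})")
        return x

    # ---------------- optode geometry ----------------

    def nearest_boundary(self, position: np.ndarray) -> tuple:
        """(centroid, outward normal) of the boundary face nearest to position."""
        position = np.asarray(position, dtype=float)
        d2 = np.sum((self.boundary_centroids - position) ** 2, axis=1)
        i = int(np.argmin(d2))
        if d2[i] > self.surface_tolerance**2:
            raise PlacementError(
                f"position {position} is {np.sqrt(d2[i]):.2f} mm from the surface "
                f"(tolerance {self.surface_tolerance:.2f} mm)"
            )
        return self.boundary_centroids[i], self.boundary_normals[i]

    def optode_weights(self, position: np.ndarray) -> tuple:
        """(nodes, weights) of an optode at a scalp surface position.

        The optode acts at the point one transport mean free path (1/mu_s' of
        the local surface tissue) beneath the position along the inward surface
        normal.  The point load / detection functional is distributed onto the
        nodes of the containing element with its barycentric coordinates, so
        optodes sit at their exact sub-voxel depth; using the same weights for
        sources and detectors keeps source-detector exchange an exact symmetry
        of the discrete Green function.
        """
        position = np.asarray(position, dtype=float)
        _, normal = self.nearest_boundary(position)
        # local surface tissue: tissue of the node nearest the surface position
        near_surf = int(np.argmin(np.sum((self.mesh.nodes - position) ** 2, axis=1)))
        tissue = int(self.mesh.node_tissue[near_surf])
        depth = 1.0 / self.props[tissue].mu_s_prime
        target = position - depth * normal
        return self._interp_weights(target)

    def _node_elements(self, node: int) -> np.ndarray:
        if not hasattr(self, "_incidence"):
            flat = self.mesh.elements.ravel()
            order = np.argsort(flat, kind="stable")
            counts = np.bincount(flat, minlength=self.mesh.n_nodes)
            starts = np.concatenate([[0], np.cumsum(counts)])
            self._incidence = (order // 4, starts)
        eidx, starts = self._incidence
        return eidx[starts[node] : starts[node + 1]]

    def _interp_weights(self, target: np.ndarray) -> tuple:
        """Barycentric interpolation weights of a point inside the mesh.

        Searches the elements incident to the nearest node; if the point falls
        marginally outside all of them (round-off at element interfaces), the
        element with the least-negative barycentric coordinate is used with
        clipped, renormalized weights.
        """
        near = int(np.argmin(np.sum((self.mesh.nodes - target) ** 2, axis=1)))
        cand = self._node_elements(near)
        best, best_min = None, -np.inf
        for e in cand:
            conn = self.mesh.elements[e]
            p = self.mesh.nodes[conn]
            try:
                lam = np.linalg.solve((p[1:] - p[0]).T, target - p[0])
            except np.linalg.LinAlgError:
                continue
            bary = np.concatenate([[1.0 - lam.sum()], lam])
            if bary.min() > best_min:
                best, best_min = (conn, bary), bary.min()
            if bary.min() >= -1e-9:
                break
        if best is None:
            return np.array([near]), np.array([1.0])
        conn, bary = best
        bary = np.clip(bary, 0.0, None)
        return conn, bary / bary.sum()


class _PermutedFactor:
    """LU factor of a symmetrically permuted matrix, solving in original order."""

    def __init__(self, lu, perm, inv_perm):
        self._lu = lu
        self._perm = perm
        self._inv_perm = inv_perm
        self.nnz = lu.nnz

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self._lu.solve(b[self._perm])[self._inv_perm]


def _nested_dissection(coords: np.ndarray, leaf: int = 64) -> np.ndarray:
    """Elimination ordering by recursive coordinate bisection with planar separators.

    Nodes are split at the median of the widest coordinate axis; nodes within
    half a lattice spacing of the cut form the separator and are ordered last.
    Assumes lattice-like node coordinates (structured voxel meshes).
    """
    n = len(coords)
    # lattice spacing: smallest nonzero coordinate gap along the first axis
    xs = np.unique(coords[:, 0])
    h = float(np.min(np.diff(xs))) if len(xs) > 1 else 1.0
    order = np.empty(n, dtype=np.int64)
    pos = 0

    def rec(idx):
        nonlocal pos
        if len(idx) <= leaf:
            order[pos : pos + len(idx)] = idx
            pos += len(idx)
            return
        c = coords[idx]
        spans = c.max(axis=0) - c.min(axis=0)
        ax = int(np.argmax(spans))
        cut = np.median(c[:, ax])
        left = idx[c[:, ax] < cut - h / 2]
        sep = idx[np.abs(c[:, ax] - cut) <= h / 2]
        right = idx[c[:, ax] > cut + h / 2]
        if len(left) == 0 or len(right) == 0:
            order[pos : pos + len(idx)] = idx
            pos += len(idx)
            return
        rec(left)
        rec(right)
        order[pos : pos + len(sep)] = sep
        pos += len(sep)

    import sys

    old_limit = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old_limit, 10000))
    try:
        rec(np.arange(n))
    finally:
        sys.setrecursionlimit(old_limit)
    return order


def _p1_element_geometry(nodes: np.ndarray, elements: np.ndarray):
    """Volumes and P1 shape-function gradients for all elements."""
    p = nodes[elements]  # (M, 4, 3)
    d = p[:, 1:, :] - p[:, :1, :]
    vol = np.linalg.det(d) / 6.0
    # gradients: rows of the inverse Jacobian give grads of phi_1..phi_3
    inv = np.linalg.inv(d)  # (M, 3, 3)
    g123 = np.transpose(inv, (0, 2, 1))  # (M, 3(node), 3(xyz))
    g0 = -g123.sum(axis=1, keepdims=True)
    grads = np.concatenate([g0, g123], axis=1)  # (M, 4, 3)
    return vol, grads


def nodal_volumes(elements: np.ndarray, vol: np.ndarray, n_nodes: int) -> np.ndarray:
    """Lumped nodal volumes V_n = sum of V_e/4 over elements containing n [mm^3]."""
    v = np.zeros(n_nodes)
    np.add.at(v, elements.ravel(), np.repeat(vol / 4.0, 4))
    return v


def _absorption_mass(elements, vol, mu_node):
    """Lumped (nodal-quadrature) absorption matrix diag(mu_n * V_n).

    Mass lumping keeps the operator an M-matrix on the non-obtuse structured
    mesh (discrete maximum principle: fluence from a positive source stays
    positive) and makes the derivative with respect to each nodal mu_a
    diagonal, which is what gives the PMDF its classical product form.
    """
    n = len(mu_node)
    return sp.diags(mu_node * nodal_volumes(elements, vol, n), format="csr")


def assemble_diffusion_system(
    mesh: TetMesh, props: OpticalProperties, surface_tolerance: float | None = None
) -> DiffusionSystem:
    """Assemble the SPD finite-element CW diffusion operator.

    Stiffness uses the element-wise diffusion coefficient of the element's
    tissue; absorption uses the nodal mu_a field (majority tissue per node);
    boundary faces carry the Robin term Phi/(2A) with A from the face tissue's
    refractive index.  A warning is emitted for low-scattering tissues (CSF)
    where the diffusion approximation is marginal; the solve proceeds.
    """
    tissues = np.unique(mesh.element_tissue)
    for t in tissues:
        if int(t) not in props.tissues:
            raise KeyError(f"no optical properties for tissue id {int(t)}")
        ti = props[int(t)]
        if ti.mu_s_prime < 10.0 * ti.mu_a:
            warnings.warn(
                f"tissue {int(t)}: mu_s'={ti.mu_s_prime:.3g}/mm is not >> "
                f"mu_a={ti.mu_a:.3g}/mm; the diffusion approximation is marginal",
                stacklevel=2,
            )

    vol, grads = _p1_element_geometry(mesh.nodes, mesh.elements)
    if np.any(vol <= 0):
        raise ValueError("mesh contains non-positively oriented elements")

    kappa_tab = np.zeros(int(tissues.max()) + 1)
    mu_a_tab = np.zeros(int(tissues.max()) + 1)
    for t in tissues:
        kappa_tab[int(t)] = props[int(t)].kappa
        mu_a_tab[int(t)] = props[int(t)].mu_a
    kappa_e = kappa_tab[mesh.element_tissue]
    node_mu_a = mu_a_tab[mesh.node_tissue]

    # stiffness: K_ij = sum_e kappa_e V_e grad_i . grad_j
    el = mesh.elements
    rows, cols, vals = [], [], []
    for i in range(4):
        for j in range(4):
            v = kappa_e * vol * np.einsum("ek,ek->e", grads[:, i, :], grads[:, j, :])
            rows.append(el[:, i])
            cols.append(el[:, j])
            vals.append(v)
    n = mesh.n_nodes
    K = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))), shape=(n, n)
    ).tocsr()

    M_abs = _absorption_mass(el, vol, node_mu_a)

    # Robin boundary term (1/(2A)) * lumped triangle mass (area/3 per node)
    bfaces = mesh.boundary_faces()
    p = mesh.nodes[bfaces]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1)
    # face tissue: majority node tissue on the face (faces are single-tissue here)
    face_tissue = np.median(mesh.node_tissue[bfaces], axis=1).astype(int)
    A_tab = {int(t): internal_reflection_parameter(props[int(t)].n) for t in tissues}
    coeff = np.array([1.0 / (2.0 * A_tab[int(t)]) for t in face_tissue])
    bdiag = np.zeros(n)
    np.add.at(bdiag, bfaces.ravel(), np.repeat(coeff * area / 3.0, 3))
    B = sp.diags(bdiag, format="csr")

    matrix = (K + M_abs + B).tocsr()

    # boundary face centroids and outward normals (normal points away from the
    # opposite node of the owning element; for a closed surface this is outward)
    centroids = p.mean(axis=1)
    normals = cross / np.linalg.norm(cross, axis=1)[:, None]
    owner = _face_owner_opposite(mesh, bfaces)
    flip = np.einsum("fk,fk->f", normals, owner - centroids) > 0
    normals[flip] *= -1.0

    if surface_tolerance is None:
        # half the largest element edge is a safe "on-surface" tolerance
        surface_tolerance = float(np.max(np.linalg.norm(p[:, 1] - p[:, 0], axis=1))) * 1.5

    return DiffusionSystem(
        mesh=mesh,
        props=props,
        matrix=matrix,
        node_mu_a=node_mu_a,
        element_kappa=kappa_e,
        boundary_centroids=centroids,
        boundary_normals=normals,
        surface_tolerance=surface_tolerance,
        robin_diagonal=bdiag,
    )


def _face_owner_opposite(mesh: TetMesh, bfaces: np.ndarray) -> np.ndarray:
    """For each boundary face, the coordinate of its owning element's 4th node."""
    # map sorted face triple -> opposite node via a dict over all element faces
    el = mesh.elements
    face_combos = [(0, 1, 2, 3), (0, 1, 3, 2), (0, 2, 3, 1), (1, 2, 3, 0)]
    tris = []
    opp = []
    for a, b, c, d in face_combos:
        tris.append(np.sort(el[:, [a, b, c]], axis=1))
        opp.append(el[:, d])
    tris = np.concatenate(tris)
    opp = np.concatenate(opp)
    order = np.lexsort((tris[:, 2], tris[:, 1], tris[:, 0]))
    tris_sorted = tris[order]
    opp_sorted = opp[order]
    # binary search each boundary face
    n = np.int64(mesh.n_nodes)
    ts = tris_sorted.astype(np.int64)
    bf = bfaces.astype(np.int64)
    keys = ts[:, 0] * n * n + ts[:, 1] * n + ts[:, 2]
    bkeys = bf[:, 0] * n * n + bf[:, 1] * n + bf[:, 2]
    pos = np.searchsorted(keys, bkeys)
    return mesh.nodes[opp_sorted[pos]]


def solve_fluence(system: DiffusionSystem, source: SourceSpec) -> FluenceField:
    """Nodal fluence for an isotropic point source beneath a scalp position."""
    phi = source.amplitude * system.solve_optode(source.surface_position)
    return FluenceField(values=phi, source=source, system=system)


def detected_intensity(field: FluenceField, detector_position: np.ndarray) -> float:
    """Detected intensity: fluence interpolated at the detector's sub-surface point."""
    nodes, weights = field.system.optode_weights(detector_position)
    return float(weights @ field.values[nodes])


def analytic_semi_infinite(
    optics: TissueOptics, rho: float, z: float = 0.0
) -> float:
    """CW fluence in a homogeneous semi-infinite medium (extrapolated-boundary dipole).

    Unit isotropic source at depth z0 = 1/mu_s' below the surface z = 0
    (z positive into the medium); negative image source mirrored across the
    extrapolated boundary at z = -zb, zb = 2 A kappa:

        Phi(rho, z) = (1/(4 pi kappa)) * ( exp(-mu_eff r1)/r1 - exp(-mu_eff r2)/r2 )
        r1 = sqrt(rho^2 + (z - z0)^2),  r2 = sqrt(rho^2 + (z + z0 + 2 zb)^2)

    Evaluated at the surface (z = 0) by default.  Units: mm^-2 per unit source.
    """
    rho = float(rho)
    if rho <= 0:
        raise ValueError("source-detector separation rho must be > 0")
    kappa = optics.kappa
    mu_eff = optics.mu_eff
    z0 = 1.0 / optics.mu_s_prime
    zb = 2.0 * internal_reflection_parameter(optics.n) * kappa
    r1 = np.sqrt(rho**2 + (z - z0) ** 2)
    r2 = np.sqrt(rho**2 + (z + z0 + 2 * zb) ** 2)
    return float(
        (np.exp(-mu_eff * r1) / r1 - np.exp(-mu_eff * r2) / r2) / (4.0 * np.pi * kappa)
    )
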