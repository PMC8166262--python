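# Methods

`nirscc` quantifies which cortical territories an fNIRS channel actually
samples — the scalp–cortex correlation (SCC) — by solving the physics of
near-infrared light transport in a layered infant head model and reducing the
result to a small set of channel-design metrics.  This note records the model,
its numerical realisation, the defaults, and the design choices that were
genuinely open.

## Forward model

Light transport is modelled by the continuous-wave diffusion approximation to
the radiative transfer equation,

    -div( kappa grad Phi ) + mu_a Phi = q,      kappa = 1 / (3 (mu_a + mu_s')),

with the partial-current (Robin) boundary condition
`kappa dPhi/dnu + Phi/(2A) = 0` on the air/tissue surface.  The internal
reflection parameter `A(n)` is computed from the tissue refractive index with
the Groenhuis polynomial approximation of the Fresnel reflection integrals
(`r_d = -1.440 n^-2 + 0.710 n^-1 + 0.668 + 0.0636 n`, `A = (1+r_d)/(1-r_d)`;
A ≈ 3.25 at n = 1.4).  Only the CW (zero modulation frequency) problem is
solved: every metric below is built from intensities and pathlengths, so phase
information would be unused.

Tissue optical properties at 800 nm (mu_a, mu_s in 1/mm; g; n):

| tissue | mu_a  | mu_s | g   | n   | mu_s' |
|--------|-------|------|-----|-----|-------|
| scalp  | 0.018 | 19   | 0.9 | 1.4 | 1.9   |
| skull  | 0.016 | 16   | 0.9 | 1.4 | 1.6   |
| CSF    | 0.0041| 0.32 | 0.9 | 1.4 | 0.032 |
| GM     | 0.048 | 5.0  | 0.9 | 1.4 | 0.5   |
| WM     | 0.037 | 10   | 0.9 | 1.4 | 1.0   |

For CSF the diffusion approximation is marginal (mu_s' is not >> mu_a); the
solver emits a warning and proceeds, treating the thin CSF shell diffusively —
the accepted approximation when no transport/Monte-Carlo hybrid is used.  An
alternative table substituting adult GM/WM coefficients is provided for
robustness studies (`adult_gm_wm_properties`).

## Discretisation

The labelled voxel volume is decomposed into 6 tetrahedra per non-air voxel
(Kuhn/Freudenthal path simplices around a common main diagonal).  With the
same diagonal in every voxel the mesh is conforming by construction, the
decomposition is volume-exact, and all simplices are non-obtuse.  Mesh quality
is reported with the Joe–Liu volume index
`qvol = 12 (3 vol)^(2/3) / sum l_ij^2` (1 for the regular tetrahedron); the
structured decomposition yields a uniform qvol of `12·0.5^(2/3)/10 ≈ 0.756` —
below what surface-adaptive meshers achieve, and reported honestly by
`mesh_statistics` rather than smoothed away.

P1 (linear) elements are used.  The stiffness term takes kappa per element
from the element's tissue.  The absorption and Robin terms are assembled with
**lumped** (nodal-quadrature) mass: `diag(mu_a,n V_n)` and `diag(area_n/(2A)·⅓)`.
Lumping has two deliberate consequences:

* the operator is an M-matrix on this non-obtuse mesh, so the discrete maximum
  principle holds and the fluence of a positive source is strictly positive
  (with consistent mass we observed sign-oscillating fluence near sources);
* the derivative of the operator with respect to each nodal absorption value
  is diagonal, which makes the adjoint sensitivity below *discretely exact*.

The nodal absorption field assigns each node the mu_a of its majority incident
voxel tissue (ties to the smaller tissue id).  kappa is computed once from the
baseline properties and held fixed under absorption perturbations — the
standard CW absorption-Jacobian convention; the mu_a-dependence of kappa is a
sub-percent effect at these contrasts and omitting it keeps the adjoint and
perturbation routes mutually consistent.

Systems are solved by sparse LU (SuperLU in symmetric mode).  The elimination
order is a geometric nested dissection computed from the lattice coordinates
of the nodes (recursive median bisection with planar separators), which on
head-sized meshes gives several-fold lower fill than generic column orderings.
Meshes above 300k nodes fall back to incomplete-LU-preconditioned CG at 1e-10
relative residual.  Every solve verifies a 1e-8 relative residual.
Absorption-perturbed systems are solved by CG preconditioned with the
factored baseline operator, warm-started at the baseline solution; the
perturbation is ~1e-4 relative, so this converges in a few iterations at 1e-12
tolerance.

## Optode model

Sources and detectors are isotropic point terms placed one transport mean free
path (1/mu_s' of the local surface tissue, 0.53 mm in scalp) beneath their
scalp positions along the inward surface normal.  The point term is
distributed onto the nodes of the containing element by barycentric
interpolation, and the detected intensity is the fluence interpolated at the
detector's sub-surface point with the same weights.  Two properties follow:
optodes sit at their exact sub-voxel depth (removing half-voxel placement
jitter that otherwise dominates short-separation errors), and source–detector
exchange is an exact symmetry of the discrete Green function, so reciprocity
holds to solver precision rather than to discretisation accuracy.

Validation: on a homogeneous medium (mu_a = 0.01, mu_s' = 1.0 /mm) the FEM
surface fluence at 2 mm voxels tracks the closed-form extrapolated-boundary
dipole solution within ~8% over 10–30 mm separations (log-intensity
correlation > 0.999).  The residual offset is dominated by the difference
between the partial-current boundary condition and the image-source
construction, not by mesh error.

## PMDF and partial pathlengths

The photon measurement density function of a channel is the sensitivity of
the log detected intensity to a local absorption change.  Discretely,

    PMDF_n = Phi_src(n) · Phi_det(n) · V_n / I_base      [mm]

with `Phi_det` the solve whose source is the detector's optode load (the
adjoint of the detection functional), `V_n` the lumped nodal volume and
`I_base` the detected baseline intensity (the Rytov normalisation).  This is
exactly the derivative of `ln I` with respect to the nodal mu_a of the lumped
operator, so summing PMDF over the nodes of a brain parcel gives that parcel's
partial pathlength (PPL), and the normalised PPL

    Lnorm_M = l_M / sum_j l_j        (brain parcels only)

is a probability simplex over parcels (sums to 1 by construction).

The direct route to the same quantity perturbs the parcel's absorption and
re-solves:  `L_abs = ln(I_base/I_pert) / delta`.  The perturbation is a
*uniform additive* increment `delta = 0.001 · mean(mu_a)` over the parcel's
nodes.  For a tissue-homogeneous parcel this is identical to multiplying the
parcel's mu_a by 1.001 and dividing by `0.001·mu_a` — the conventional "0.1%
perturbation" definition — but it remains the exact first-order estimator of
the parcel PPL when a parcel spans GM and WM, whose mu_a differ by ~25% (a
multiplicative perturbation normalised by a single reference mu_a would bias
the mixed-parcel estimate by several percent).  The adjoint and perturbation
routes agree to ~1e-4 relative (the residual is the second-order term of the
0.1% perturbation), and the test-suite uses each as the other's oracle.

## Channel metrics

For each (age, fiducial, orientation, SD distance):

* **NCBR** — number of parcels with `Lnorm > 0.05` (strict inequality).
* **MLCBR** — parcel with the largest Lnorm; ties break to the smallest parcel
  id (never observed at working precision).
* **selectivity** — `Lnorm` of the MLCBR: the probability share of the channel
  signal attributable to its best parcel.
* **sensitivity** — `L_abs` of the MLCBR in mm of brain pathlength.
* **consistency** — across the three age models at fixed (fiducial,
  orientation, distance): completely consistent if all three MLCBRs agree
  (this takes precedence), otherwise the matching pair category (0–1, 0–2,
  1–2), otherwise inconsistent.

Zoning for probe design: a channel is **red** if sensitivity < 3 mm
(sensitivity takes precedence — too little brain signal to use), otherwise
**green** if selectivity > 0.4, else **yellow**.  Equality at a boundary goes
to the non-extreme class (sensitivity exactly 3 is not red; selectivity
exactly 0.4 is yellow).  A robustness variant uses thresholds (4, 0.5).
`zone_ratios` reports the per-distance zone shares over a fiducial population.

## Synthetic phantom: what it emulates and what it does not

The phantom is a sphere of concentric shells with age-specific layer
thicknesses: scalp 3.5/4/4 mm and skull 2.2/3/3.8 mm for 0/1/2-year-olds, a
2 mm CSF shell and a 3 mm cortical (GM) shell over a WM core.  Outer radii
(56/73/77 mm) follow typical head circumferences at those ages (35/46/48.5 cm).
CSF and GM thicknesses are fixed across ages at values representative of
infant anatomy; they are parameters of `PhantomSpec`, not fitted quantities.
The brain is parcellated into angular sectors split by hemisphere (default 45
per hemisphere, echoing a 90-region whole-brain atlas), with equal-area
latitude bands subdivided in azimuth; parcel ids are deterministic functions
of position, so all three ages share one parcellation namespace by
construction.

A sphere was chosen over a realistic head geometry deliberately: every metric
above is geometry-agnostic, and the sphere admits closed-form oracles (shell
volumes, great-circle geodesics, exact mirror symmetry) that a realistic
surface does not.  Landmarks (nasion, inion, periauricular points) are the
equatorial compass points of the fitted scalp sphere; the 61 fiducials of the
10-10 system are constructed from them with the standard 10% geodesic
subdivisions (sagittal and coronal arcs, the circumferential ring through
Fpz/T3/Oz/T4, and intermediate coronal arcs through their midline points).
Because the scalp is a sphere, all arcs are exact circle sections of the
fitted surface rather than marched discrete geodesics — exact where a
voxel-surface march carries several percent of metric error.  Real segmented
label volumes in NIfTI-1 can be substituted for the phantom
(`load_voxel_model_nifti`, or `RunConfig.nifti_inputs`); the 10-10
construction then still assumes an approximately convex, sphere-like scalp.

Consequences for interpretation: passing tests on the sphere phantom validate
the transport physics, the sensitivity calculus and the metric definitions.
They do not probe effects that require realistic anatomy — cortical folding,
regionally varying layer thicknesses, the longitudinal fissure (where real
heads show inconsistent MLCBRs), or atlas-specific parcel shapes.  Absolute
metric values on the phantom are therefore not comparable to values computed
on real infant templates; the qualitative structure (trends with SD distance,
the sensitivity/selectivity trade-off, zone shapes) is.

SD pairs are centred on a fiducial with the source and detector at ±d/2
*geodesic* (not chord) distance along the circumferential direction (the
horizontal ring tangent) or the vertical direction (the surface tangent
towards Cz); at Cz itself these degenerate and the coronal and sagittal
directions are used.  Distances 10–30 mm in 5 mm steps are the study grid.

## Problem sizes and determinism

Defaults run the three age phantoms at 2 mm voxels (about 0.1–0.2 M nodes
each).  The test-suite uses reduced problem sizes chosen for desk-scale
runtimes: a 40 mm sphere at 2 mm voxels (~37k nodes) for sensitivity-calculus
checks, an 84×84×33 mm slab at 2 mm for solver validation, and the 0-yo
phantom at 3 mm voxels (~31k nodes) for the full 61-fiducial trend sweep.
Distance trends (PMDF extent, NCBR, sensitivity up; selectivity, red-zone
share down) are asserted on the across-fiducial population mean, matching the
population-level character of the underlying observations; per-channel curves
can show ±1-count NCBR or sub-percent selectivity wiggles from parcel
discretisation.

Everything is deterministic given the configuration; the run seed is recorded
in the manifest (and reserved for future stochastic extensions) but no stage
of the present pipeline draws random numbers.  Determinism is tested
bit-for-bit on the emitted tables.

## Known limitations

* Diffusive treatment of CSF (no radiosity/transport hybrid) biases
  sensitivity distributions in the CSF shell; thin-shell phantoms keep the
  effect small but it is not zero.
* The structured mesh has uniform element quality 0.756 and axis-aligned
  staircase surfaces; surface curvature enters only through the voxelisation.
* Intensities are reported in arbitrary units (unit-amplitude optode loads);
  only ratios and pathlengths are physically meaningful, and only those are
  used by the metrics.
* No chromophore spectroscopy, image reconstruction, or inferential
  statistics: the pipeline ends at descriptive channel metrics and reference
  tables.
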