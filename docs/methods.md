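# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments can and cannot show. It states no result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Constitutive model

The vessel wall and fibrous cap are hyperelastic, anisotropic and nearly
incompressible. The strain-energy density is a modified Mooney–Rivlin
form with an exponential isotropic term and an exponential
fiber-reinforcement term along the circumferential direction `n_c`:

    W = c1 (Ī1 − 3) + c2 (Ī2 − 3) + D1 [exp(D2 (Ī1 − 3)) − 1]
      + (K1/K2) {exp[K2 (I4 − 1)²] − 1} + (κ/2)(J − 1)²

Choices that need stating:

* **Isochoric split.** Ī1 = J^(−2/3) I1 and Ī2 = J^(−4/3) I2 are the
  isochoric invariants of C = FᵀF; the quadratic volumetric penalty gives
  bulk modulus κ at the reference state. With *full* invariants and a pure
  (J−1)² penalty the printed parameter sets would leave the reference
  state stressed (σ(I) ≈ 350 kPa for the vessel set, since
  c1 + 2c2 + D1·D2 ≠ 0); the multiplicative split — the standard treatment
  in nearly-incompressible commercial FE implementations of this law —
  makes W(I) = 0 and σ(I) = 0 exactly. The fiber invariant I4 = n_c·C n_c
  is kept full (not isochoric), the usual convention for fiber terms.
* **Fiber normalization and tension switch.** The fiber term uses the
  Holzapfel-type normalization (K1/K2){exp[K2(I4−1)²] − 1} so it vanishes
  at I4 = 1, and is active only in fiber tension (I4 > 1). The switch is
  value- and slope-continuous at I4 = 1.
* **Parameters** (kPa): vessel/cap c1 = −1312.9, c2 = 114.7, D1 = 629.7,
  D2 = 2.0, K1 = 35.9, K2 = 23.5; lipid 0.5, 0, 0.5, 1.5; calcification
  92.0, 0, 36.0, 2.0. The negative c1 is intentional in this family; the
  package checks at preset load time that the 6×6 small-strain tangent at
  identity is positive definite (it is: shear modulus
  2(c1+c2+D1·D2) = 122.4 kPa for the vessel set).
* **Volumetric modulus.** κ defaults to 3000 kPa (bulk/shear ≈ 25,
  Poisson ratio ≈ 0.48): "nearly incompressible" without ill-conditioning
  at desk scale. Configurable per material.
* **Range guard.** The exponentials overflow for extreme stretch; the
  evaluation raises an explicit range error beyond exponent 60 rather
  than returning inf, and the Newton line search treats that like an
  element inversion.

Stress is σ = J⁻¹ F S Fᵀ with S = 2∂W/∂C; the material tangent used by
the solver is obtained by complex-step differentiation of S (exact to
round-off, verified against finite differences in the tests).

## Kinematics: plane strain and the thin-layer model

Cross-section models are solved with in-plane displacements and a
prescribed uniform axial stretch λ_z (generalized plane strain):

* 2D models use λ_z = 1, i.e. plane strain. The source model family never
  states its 2D kinematic assumption; plane strain is the standard choice
  for vessel cross-sections and is the λ_z → 1 limit of the thin-layer
  model, so both variants live in one formulation.
* The thin-layer (TL) model is defined as a 0.5 mm one-element extrusion
  of the slice whose flat axial faces are displacement-controlled to
  impose λ_z = 1/0.9 (undoing the 10 % axial shrink). Because the
  geometry, loads and materials are z-invariant and the axial faces stay
  flat, that 3D problem reduces *exactly* to the in-plane problem with
  prescribed λ_z; the package solves the reduced problem and recovers the
  axial Cauchy stress from the 3D law. The plane-strain-equivalence test
  (λ_z = 1) therefore holds to machine precision rather than "within 1%".

## Solid FEM

* **Meshing.** Nested contours are meshed by a structured, component-
  fitted strategy: rays from the lumen centroid; per-ray radial
  breakpoints at the lumen, outer-wall and inclusion crossings; one shared
  radial "inclusion band" anchored per-ray to the crossing radii (the
  generator guarantees at most one inclusion per ray since lipid and
  calcification occupy disjoint arcs). Quads are split into triangles and
  promoted to quadratic (P2) elements with straight edges. Region labels
  inside the band are assigned by polygon overlap with a greedy
  area-correcting pass, so mesh region areas match the polygon areas to
  O(h²) — below 1 % once h ≲ 0.15 mm for these geometries; meshing fails
  hard beyond a 5 % mismatch. The construction requires contours that are
  star-shaped about the lumen centroid, which IVUS-like cross-sections
  are.
* **Solver.** Total-Lagrangian Newton iteration, 6-point quadrature,
  analytic assembly with the complex-step material tangent. Lumen
  pressure is a follower load on the deformed boundary; in 2D its exact
  load stiffness is constant per edge and is included, so convergence is
  quadratic. Default tolerance: residual ≤ 1e−8 × ‖f_ext‖. Loading is
  incremental (default 10 steps) with adaptive sub-stepping: a failed
  increment is halved and retried, with a backtracking line search that
  rejects element inversion, constitutive range errors, and residual
  blow-ups. A stationary-step criterion (‖du‖ ≤ 1e−13 ‖u‖) accepts
  near-rigid problems that hit the round-off floor above the relative
  tolerance.
* **Constraints.** The follower pressure on a closed boundary is exactly
  self-equilibrated (zero net force and moment), so the three rigid-body
  modes are removed by three point constraints on the outer wall whose
  reactions vanish at equilibrium.
* **Stress recovery and lumen sampling.** Quadrature-point stresses and
  Green strains are projected onto the nodal basis by a global L2
  projection (O(h²) boundary accuracy, against O(h) for plain element
  averaging). PWS/PWSn at the lumen are the maximum principal values of
  the interpolated 3D tensors at 100 points uniform in deformed-boundary
  arc length, ordered CCW from where the boundary crosses the +x ray from
  the deformed lumen centroid — the same convention for every variant, so
  pointwise comparisons are aligned by arc-length fraction.
* **Mesh independence.** The study rule: refine h by 10 % per step until
  the mean lumen PWS changes by less than 1 % between successive meshes;
  the sequence is recorded. On the ring benchmark the default start
  (h = 0.35 mm) terminates after one refinement check and lands within
  2 % of the independent ODE oracle.

## Zero-load geometry recovery

The imaged cross-section is pressurized, so using it as a stress-free
reference overestimates stress. The package recovers a no-load surrogate
in two steps:

* **Axial:** the vessel is shortened by the fixed 10 %; in-plane
  coordinates scale by 1/√0.9 so tissue volume (wall area × length) is
  conserved, and the solver later applies λ_z = 1/0.9.
* **Circumferential:** a single per-slice ratio k scales the lumen about
  its centroid; the outer contour follows by wall-area conservation and
  inclusions by radial-fraction mapping (nesting preserved by
  construction). k is found by bisection on [0.7, 1.0] so that
  re-pressurizing at the imaging pressure recovers the in vivo lumen area
  within 0.5 % (relative). Bisection is preferred over a faster
  root-finder because each function evaluation is a full FEM solve and
  the bracket is known; typical searches take 5–8 evaluations. Matching
  is by lumen *area*; the Hausdorff distance between the re-pressurized
  and imaged lumen contours is reported as a shape diagnostic. A failed
  low-k solve (material cannot be re-inflated to the target) is treated
  as undershoot; if no ratio in the bracket works the search fails with
  the achieved interval.
* The imaging pressure (the pressure at acquisition) is not generally
  known; it defaults to the diastolic minimum and is recorded prominently
  in every report, since it directly changes the shrink ratio.
* Opening-angle residual stress is excluded (a known limitation of the
  shrink–stretch construction).

## Flow surrogate

The full 3D unsteady ALE Navier–Stokes/FSI system is deliberately
replaced by fully developed laminar axial flow on each cross-section:
−μ∇²w = G with w = 0 on the lumen boundary. This is the central scope
reduction of the package and every FSS output carries the stamp
`surrogate: fully-developed`.

* Blood viscosity defaults to μ = 0.04 Poise; the drive defaults to a
  prescribed flow rate Q = 1 mL/s (a typical mean coronary flow), the
  same Q for every variant being compared, so FSS differences isolate
  geometry. A pressure-gradient drive is available instead.
* Wall shear stress μ|∂w/∂n| is extracted from the consistent nodal
  reactions, lumped per boundary edge (half of each endpoint vertex plus
  the midside node, divided by edge length). This is exactly conservative
  and O(h²); the raw per-node reaction split is an O(1) discrete artifact
  and is not used pointwise. Verified to 0.5 % against the Poiseuille
  circle and 1 % against the elliptic-duct closed form.
* The coupled (FSI-analog) variant is one-way: solve the structure on the
  preconditioned geometry, then flow on the deformed lumen. There is no
  feedback of flow traction on the wall — lumen pressure already
  dominates wall loading — so the structural fields of the coupled and
  structure-only variants coincide by construction.

## Synthetic cohort

No real VH-IVUS segmentations are publicly deposited, so the study runs
on a seeded synthetic cohort emulating them: area-preserving elliptical
lumens with eccentric center offset and band-limited (low-harmonic)
radial noise; a lipid core on the thick-wall side whose inner boundary is
the exact Euclidean offset of the lumen by the cap thickness, tapering to
zero at the arc ends; an optional mid-wall calcification on a disjoint
arc. Defaults draw diastolic pressures from 60–97 mmHg and systolic from
110–144 mmHg (the range reported for real vulnerable-plaque patients),
lumen radii 1.2–1.8 mm, wall thickness 0.8–1.3 mm, caps 0.08–0.3 mm, and
produce area stenoses of roughly 35–65 % and plaque burdens of 55–80 %.
Slice spacing defaults to 0.5 mm (the TL thickness; the acquisition
spacing is not otherwise constrained).

The study size is deliberately desk-scale: 7 vessels with 2–4 slices each
(the default `n_slices_range`), structural meshes at h = 0.35 mm and 6
load increments for the cohort study, finer meshes (h = 0.1–0.2 mm) for
the oracle benchmarks. A full 5-variant, 2-phase cohort comparison runs
in a few minutes on one CPU.

What the synthetic cohort does **not** emulate: real segmentation noise
statistics and inter-observer variability, non-star-shaped lumens,
multi-layer wall structure, vessel curvature and cyclic bending, axial
plaque continuity (slices are mechanically independent), and pulsatile
flow. Passing tests therefore validate the numerics and the *directions*
of model differences under these conditions, not patient-specific
magnitudes.

## Validation oracles

* **Ring inflation ODE.** Exactly incompressible plane-strain inflation
  of a thick-walled ring reduces to r² = R² − Ri² + ri² and
  p = ∫ λ W′(λ) dr/r; a scalar root-find inverts it and radial
  integration gives σ_rr and σ_θθ. Fiber term included. Independent of
  the FEM path; agreement within 2 % at mid-wall (the residual gap is
  dominated by the penalty compressibility, κ = 3000 kPa vs the oracle's
  exact incompressibility).
* **Small-load closed forms.** The isotropic calcification preset is
  checked against the classical Lamé thick-wall solution. The vessel
  preset's tangent at identity is cylindrically *orthotropic* (the
  tension-active fiber stiffens the hoop direction), so its correct
  small-load limit is the Lekhnitskii power-law ring solution
  (u = A r^k + B r^−k, k = √(C_θθ/C_rr)), built here from the numerically
  probed 6×6 tangent of W; the classical isotropic formula is not the
  matching linearization for that preset.
* **Flow closed forms.** Poiseuille (circle) and the elliptic-duct
  solution, pointwise.
* **Statistics.** The pointwise Δ/relative-error implementation is
  checked against a literal brute-force recomputation to 1e−12 and the
  worked example p = [1,2,3], q = [2,3,4] → RelErr = 50 % exactly.

## Model-comparison study and a known negative result

The cohort study compares M2-vs-M1 (pre-shrink effect), M1/M5-vs-FSI
(2D vs thin-layer vs coupled), and M7-vs-FSI (flow-only vs coupled,
Max/Min/Ave-FSS at systole and diastole), with model p as the base of
each relative error and all aggregation pooled over points (never means
of means). Under the study conditions: skipping the pre-shrink raises
PWS on every slice; the thin-layer variant is closer to the coupled
surrogate than the 2D variant (exactly coincident, by the one-way
coupling); and flow-only FSS exceeds coupled FSS at systole.

One directional expectation does **not** reproduce: at systolic pressure
the Min-FSS summary is not the most discrepant of the three FSS summaries
between flow-only and coupled variants (measured: Max > Ave > Min). With
a fixed flow rate, a geometrically similar inflation shifts all three
summaries equally, and the ordering is decided purely by shape change; at
systole the thin-wall, high-FSS side inflates most, making Max-FSS the
most sensitive. At diastole — where the coupled lumen matches the imaged
area and only residual shape differences remain — Min-FSS *is* the
largest disagreement, i.e. the geometric Min-FSS sensitivity is present.
The strong systolic Min-FSS fragility reported for real 3D models arises
from pulsatile, near-separation and bending flow physics that the
fully-developed per-slice surrogate excludes by design; the corresponding
acceptance test is left failing rather than weakened, and the acceptance
script reports the measured disagreements at both phases.

## Other limitations

* Viscoelasticity, damage, layer-specific laws, fiber dispersion and
  patient-specific material properties are out of scope.
* Contours must be star-shaped about the lumen centroid (true of the
  generator's output and typical IVUS segmentations; not of extreme
  dissection geometries).
* Per-slice independence means no axial stress transfer between slices.
* The comparison tables report descriptive errors only; no hypothesis
  testing across patients.
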