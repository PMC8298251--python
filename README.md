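# plaquemech

Mechanical analysis of atherosclerotic coronary plaque cross-sections, and
quantification of how much the common modelling shortcuts change the
answer.

Image-based plaque models are used to estimate plaque wall stress (PWS),
wall strain (PWSn) and flow shear stress (FSS) — quantities linked to
plaque progression and rupture risk. In practice groups choose very
different model families: 2D cross-section models with or without a
zero-load ("pre-shrink") geometry recovery, cheap 3D thin-layer (TL)
models, structure-only models, fluid-only models, or full fluid–structure
interaction (FSI). `plaquemech` implements a desk-scale version of this
whole model family on synthetic IVUS-like cross-sections so that the
differences between variants can be computed, not guessed.

The package is aimed at cardiovascular-biomechanics researchers and
students who want a transparent, fully scriptable reference implementation
of the cross-section pipeline: geometry → preconditioning → hyperelastic
FEM → lumen sampling → model-comparison statistics.

## What is inside

* **Constitutive model.** Vessel wall / fibrous cap as a modified
  Mooney–Rivlin solid with an exponential isotropic term and an
  exponential circumferential-fiber term,

      W = c1(Ī1−3) + c2(Ī2−3) + D1[exp(D2(Ī1−3)) − 1]
        + (K1/K2){exp[K2(I4−1)²] − 1} + (κ/2)(J−1)²

  with isochoric invariants Ī1, Ī2, fiber invariant I4 = n_c·C n_c, and a
  volumetric penalty (near-incompressibility). Lipid core and
  calcification are isotropic (K1 = 0). Parameter presets: vessel/cap
  c1 = −1312.9, c2 = 114.7, D1 = 629.7 kPa, D2 = 2.0, K1 = 35.9 kPa,
  K2 = 23.5; lipid 0.5/0/0.5 kPa, D2 = 1.5; calcification 92/0/36 kPa,
  D2 = 2.0.
* **Solid FEM.** Component-fitted structured meshing of nested contours
  (lumen / wall / lipid / calcification), total-Lagrangian Newton solves
  with quadratic triangles, follower lumen pressure, traction-free outer
  wall; 2D plane strain or thin-layer kinematics (0.5 mm extrusion with a
  prescribed axial stretch 1/0.9 after the 10 % axial shrink).
* **Preconditioning.** Circumferential pre-shrink found by bisection so
  that re-pressurizing the shrunk slice at the imaging pressure recovers
  the in vivo lumen area (wall area conserved), plus the fixed 10 % axial
  shrink–stretch.
* **Flow surrogate.** Fully developed laminar axial flow
  (−μ∇²w = G, w = 0 on the wall) on arbitrary lumen cross-sections at a
  prescribed flow rate; wall shear stress from the consistent boundary
  flux, reported in dyn/cm². Coupled variant: structure first, then flow
  on the deformed lumen (one-way FSI surrogate — every FSS output is
  stamped as such).
* **Comparison statistics.** For aligned 100-point lumen profiles of
  models p and q: Δᵢ = |xₚᵢ − x_qᵢ|, MeanΔ, Mean xₚ, and
  RelErr = MeanΔ / Mean xₚ × 100 %, pooled over points at slice, patient
  and cohort level.
* **Synthetic cohort.** A seeded generator of VH-IVUS-like segmented
  slices (eccentric lumen, lipid core behind a controllable fibrous cap,
  optional calcification) stacked into multi-slice vessels with
  per-patient diastolic/systolic pressure ranges, plus the standard
  severity metrics (area stenosis, plaque burden).

Model variants: `M1` (2D + pre-shrink), `M2` (2D, no shrink), `M5`
(thin-layer structure-only), `FSI` (thin-layer + one-way flow coupling),
`M7` (flow-only on the imaged lumen).

## Worked example

```python
import numpy as np
from plaquemech import (benchmarks, build_mesh, solve_static, SolveConfig,
                        sample_lumen, material_preset, find_circ_shrink)
from plaquemech.units import mmhg_to_kpa

# an idealized coronary cross-section: 1.5 mm lumen radius, 1.5 mm wall
slice_ = benchmarks.ring_slice(r_inner=1.5, r_outer=3.0)
wall = material_preset("vessel")

# recover the zero-load geometry: shrink until re-pressurizing at the
# imaging pressure (100 mmHg) reproduces the imaged lumen area
shrink = find_circ_shrink(slice_, {"wall": wall}, mmhg_to_kpa(100), h=0.3)
print(f"circumferential shrink ratio: {shrink.circ_shrink_ratio:.4f} "
      f"({shrink.iterations} bisection steps, "
      f"area error {100*shrink.achieved_area_error:.2f}%)")

# systolic stress with the pre-shrink (M1-style) ...
cfg = SolveConfig(pressure=mmhg_to_kpa(120))
m1 = sample_lumen(solve_static(build_mesh(shrink.shrunk_slice, 0.2),
                               {"wall": wall}, cfg))
# ... and treating the imaged geometry as stress-free (M2-style)
m2 = sample_lumen(solve_static(build_mesh(slice_, 0.2), {"wall": wall}, cfg))
over = 100 * (m2.PWS.mean() - m1.PWS.mean()) / m1.PWS.mean()
print(f"mean PWS with pre-shrink:    {m1.PWS.mean():.1f} kPa")
print(f"mean PWS without pre-shrink: {m2.PWS.mean():.1f} kPa ({over:+.1f}%)")
```

prints

```
circumferential shrink ratio: 0.9625 (5 bisection steps, area error 0.40%)
mean PWS with pre-shrink:    36.3 kPa
mean PWS without pre-shrink: 37.5 kPa (+3.2%)
```

The shrink ratio says the imaged (pressurized) ring must be contracted to
96.25 % of its circumference to act as a zero-load reference; skipping
that step and loading the imaged geometry directly overestimates the mean
wall stress — here by 3.2 % on a thick-walled idealized ring, and by more
on eccentric thin-cap plaques.

The same study runs from the shell on a whole synthetic cohort:

```bash
plaquemech generate --config examples/study.yaml --out cohort/
plaquemech run --config examples/study.yaml --variant M1 --vessel cohort/P1.csv --out profiles/
plaquemech compare --config examples/study.yaml --pairs M1:M2,FSI:M5 --report report/
```

`report/` then holds per-patient comparison tables
(`M1_vs_M2_PWS.csv`, …), a human-readable `summary.txt`, and a
`provenance.json` with seeds, configs and shrink ratios.

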