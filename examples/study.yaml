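# Example study configuration: a small synthetic cohort and the four
# standard model-variant comparisons.
cohort:
  n_patients: 2
  base_seed: 42
  n_slices_range: [2, 3]
  slice_spacing: 0.5          # mm
solver:
  mesh_h: 0.35                # mm
  load_steps: 6
preconditioning:
  tol: 0.005                  # relative lumen-area tolerance
  imaging_pressure: p_min     # acquisition pressure rule
flow:
  viscosity_poise: 0.04
  flow_rate_ml_s: 1.0
comparison:
  pairs: ["M1:M2", "FSI:M5"]
  n_points: 100
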