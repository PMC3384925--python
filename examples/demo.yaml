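# Demo: synthetic 308 vs 58 cohort, 10 metabolites, 6 planted markers.
seed: 1
outdir: demo_out
design:
  n_group1: 308
  n_group2: 58
  informative_indices: [1, 2, 4, 5, 6, 10]
  effect_size: 2.0
grid:
  sigma: [0.1, 0.2, 0.5, 1.0, 2.0, 5.0, 10.0]
  ao: [1, 2, 3]
  folds: 10
spa:
  N: 1000
  R: 0.8
  Q: 8
  p_threshold: 0.01
clinical_variables:
  - {name: age, kind: continuous, group1: [70.32, 9.08], group2: [67.84, 10.84]}
  - {name: bmi, kind: continuous, group1: [25.28, 2.96], group2: [26.10, 3.11]}
  - {name: hyperlipidemia, kind: binary, group1: 0.393, group2: 0.810}
  - {name: obese, kind: binary, group1: 0.513, group2: 0.603}
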