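# Desk-scale profile: three arms on a 600-column synthetic cohort.
# For the full-scale profile raise n_iterations / n_repetitions to 250 and
# n_features_total to 1240 (and widen n_grid, e.g. [10, 20, 30, 50, 75, 100,
# 150, 200, 250, 300]).
arms: [T1, T2, T1+T2]
cohort_spec:
  n_features_total: 600
  n_informative_per_class: 10
  effect_size: 2.0
  missing_fraction: 0.15
  n_redundant_pairs: 30
selection:
  n_iterations: 25
  n_grid: [150, 200]
final:
  n_repetitions: 25
output_dir: results
master_seed: 1
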