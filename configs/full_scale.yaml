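# Full-budget profile: cohort-shaped data, default search budgets
# (25 crows x 100 iterations, 10-fold CV fitness, ten runs). Slow.
synth:
  n_samples: 11000
  n_features: 149
  n_informative: 15
  prevalence: 0.09472727272727273
  effect_size: 1.5
  seed: 0
fs:
  n_crows: 25
  t_max: 100
sae:
  hidden_sizes: [32]
eo:
  n_particles: 10
  max_iter: 10
n_runs: 10
test_fraction: 0.3
cv_folds: 10
surrogate_folds: 5
master_seed: 0
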