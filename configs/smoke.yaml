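# Desk-scale profile: small synthetic cohort, reduced search budgets.
synth:
  n_samples: 600
  n_features: 30
  n_informative: 6
  prevalence: 0.3
  effect_size: 1.5
  seed: 0
fs:
  n_crows: 6
  t_max: 8
sae:
  hidden_sizes: [12]
  pretrain_epochs: 15
  finetune_epochs: 100
eo:
  n_particles: 4
  max_iter: 2
n_runs: 2
test_fraction: 0.3
cv_folds: 3
surrogate_folds: 3
master_seed: 0
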