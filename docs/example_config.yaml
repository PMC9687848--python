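# Full run configuration consumed by `xcsr-extubation run-all --config ...`
# (and by every other subcommand).  All fields shown with their defaults;
# `generator.seed` is the only mandatory field.

generator:
  seed: 1                 # mandatory: drives cohort sampling
  n_total: 262            # recruited records before exclusion
  failure_fraction: 0.17543859649122806   # 40/228
  mode: table             # "table" or "planted_rule"
  planted_rule: []        # [[variable, low, high], ...] for planted_rule mode
  planted_features: []
  label_noise: 0.0        # flip probability for planted labels
  n_missing_records: 34   # records receiving one missing value

xcsr:
  epochs: 100
  N: 1500
  beta: 0.2
  alpha: 0.1
  nu: 0.1
  eps_0: 10.0
  theta_ga: 25.0
  chi: 0.8
  mu: 0.04
  theta_del: 20
  delta: 0.1
  theta_sub: 20
  p_dontcare: 0.5
  p_init: 10.0
  eps_init: 0.0
  f_init: 10.0
  theta_mna: 2
  reward_correct: 1000.0
  reward_incorrect: 0.0
  s_r: 0.5                # covering spread cap, normalized scale
  m_i: 0.1                # mutation step, normalized scale
  seed: 0                 # overridden per run by the seed schedule
  crossover: uniform      # or "per_locus"

n_runs: 10                # seed schedule 1..n_runs unless `seeds` given
stable:
  min_experience: 20
  require_match: true
  enabled: true
output_dir: xcsr_run
log_level: INFO
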