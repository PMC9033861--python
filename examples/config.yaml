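# Example pipeline configuration:
#   sociometer simulate --config examples/config.yaml
#   sociometer fit      --config examples/config.yaml --data sociometer_out/cohort.csv
#   sociometer compare  --config examples/config.yaml --fits sociometer_out/fits.csv
#   sociometer recover  --config examples/config.yaml
global_seed: 1
output_dir: sociometer_out
log_level: INFO

design:
  n_groups: 4
  approval_rates: [0.15, 0.30, 0.70, 0.85]
  raters_per_group: 48

simulate:
  model: belief
  n_participants: 10

fit:
  models: [associative, belief]
  n_starts: 129

recover:
  models: [associative, belief]
  n_participants: 30
  thresholds:
    min_rho: 0.7
    min_win_frac: 0.5
    params:
      associative: [eta, gamma, w1]
      belief: [w, varsigma, m_se]
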