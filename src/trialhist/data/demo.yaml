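# Demo pipeline configuration: a small synthetic cohort that exercises
# every stage end-to-end in well under a minute.
seed: 20260904
simulate:
  n_mice: 1
  n_sessions: 3
  n_units_per_session: 4
  n_trials: 220
  beta0: 0.0
  beta_odor_L: 3.0
  beta_odor_R: 3.0
  beta_choice: [0.7]
  beta_outcome_L: [0.3]
  beta_outcome_R: [-0.3]
  modulation_amplitude: 5.0
  baseline_rate: 10.0
behavior:
  n_repeats: 10
  pair: simple_vs_ext1
preference:
  n_perm: 200
  lags: [0, 1, 2]
  variables: [choice, outcome]
sliding:
  align_event: valve_open
  window: [-0.5, 1.0]
link:
  n_perm: 200
  fit: line
inactivation:
  n_sets: 2
  delta_bias: 0.8
  choice1_scale: 0.5
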