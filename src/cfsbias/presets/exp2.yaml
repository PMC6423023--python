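# Monocular control arm: small, monotonically decaying congruence effects,
# faster and less variable detection RTs (no interocular suppression).
design:
  n_participants: 36
  n_sequences: 32
  reps_per_sequence: 6
  n_blocks: 12
  arm: monocular
  max_rt: 5000.0
  seed: 0
profile:
  delta: [0.034, 0.010, 0.013, 0.001, 0.002, 0.003]
  base_rt_mean: 1100.0
  base_rt_cv: 0.135
  subject_sd: 0.2
  recog_params: [0.87, 0.11, 0.5]
  loc_error_rate: 0.007
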