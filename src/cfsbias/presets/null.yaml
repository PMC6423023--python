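# Zero-effect profile for calibration runs (otherwise matches the
# suppression arm's noise regime).
design:
  n_participants: 36
  n_sequences: 32
  reps_per_sequence: 6
  n_blocks: 12
  arm: suppression
  max_rt: 5000.0
  seed: 0
profile:
  delta: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
  base_rt_mean: 1452.0
  base_rt_cv: 0.45
  subject_sd: 0.2
  recog_params: [0.90, 0.10, 0.5]
  loc_error_rate: 0.018
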