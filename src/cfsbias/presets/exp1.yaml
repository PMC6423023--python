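# Dichoptic-suppression arm: U-shaped congruence-effect profile.
# delta solved from the reported per-repetition %-effects; base_rt_mean from
# the reported 61 ms / 4.2% overall pairing; noise CV from the reported
# between-subject SDs of the normalized effect.
design:
  n_participants: 36
  n_sequences: 32
  reps_per_sequence: 6
  n_blocks: 12
  arm: suppression
  max_rt: 5000.0
  seed: 0
profile:
  delta: [0.079, 0.019, 0.028, 0.001, 0.052, 0.071]
  base_rt_mean: 1452.0
  base_rt_cv: 0.45
  subject_sd: 0.2
  recog_params: [0.90, 0.10, 0.5]
  loc_error_rate: 0.018
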