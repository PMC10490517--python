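# Two-subject toy configuration for the README walk-through.
# Short sessions, no obstacles, default (moderate) effect sizes.
cohort:
  n_subjects: 2
  manual_duration_s: 60.0
  adas_duration_s: 60.0
  obstacle_positions_m: []
  track_length_m: 100.0
  seed: 5

preprocessing:
  window_s: 3.0
  asr:
    calibration_window_s: 20.0

model:
  max_epochs: 1
  early_stopping_patience: 1
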