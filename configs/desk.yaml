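# Desk-scale recipe: trains in minutes on one CPU core.
seed: 0
detector:
  n_harmonics: 6
  width: 16
  pyramid_levels: 3
  learning_rate: 1.0e-3
  weight_decay: 0.0
  batch_size: 8
  epochs: 20
  crop_size: 128
  target_scale: 64.0
synth:
  height: 128
  width: 128
  n_cells_lambda: 6.0
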