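# Published training recipe: Adam, initial learning rate "10e-4", weight
# attenuation "10e-8", batch size 256, 90 epochs, random 256x256 crops with
# random horizontal/vertical flips.  The shorthand "10e-4"/"10e-8" is read
# as 1e-4/1e-8; a literal reading would give 1e-3/1e-7.
# This scale is far beyond a 1-CPU sandbox; it is provided for completeness.
seed: 0
detector:
  n_harmonics: 6
  learning_rate: 1.0e-4
  weight_decay: 1.0e-8
  batch_size: 256
  epochs: 90
  crop_size: 256
  target_scale: 256.0
synth:
  height: 256
  width: 256
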