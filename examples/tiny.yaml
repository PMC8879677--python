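# Smoke-scale pipeline configuration: 3 upper-thoracic vertebrae, 32^3
# patches, 2 training epochs. See docs/methods.md for the study-scale setup.
phantom:
  n_vertebrae: 3
  grid_size: 32
  body_radius_range: [5.0, 8.0]
  process_length_range: [6.0, 9.0]
model:
  patch_size: 32
  out_size: 32
  n_batch_vertebrae: 3
train:
  epochs: 2
n_spines: 3
seed: 21
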