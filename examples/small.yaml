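# A desk-scale run configuration: width-scaled model, shortened training.
# Omitted keys fall back to the full-scale defaults (64 kernels, 128x128
# patches, 10,000 iterations).

synthetic:
  n_train_patients: 12
  n_test_patients: 10
  volume_shape: [10, 88, 88]

model:
  channels_per_pathway: [2, 1]
  kernels_per_conv: 16
  head_channels: [32, 2]

train:
  iterations: 1500
  patch_size: 64
  checkpoint_every: 750

finetune:
  iterations: 100
  patch_size: 64
  slice_mode: all_lesion
  weighting: none
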