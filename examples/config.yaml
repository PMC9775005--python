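# Example pipeline configuration consumed by the CLI (--config).
# Any omitted key falls back to the library default.

filter:
  highpass_cutoff_hz: 1.0
  notch_band_hz: [48.0, 52.0]
  bandpass_band_hz: [0.5, 35.0]
  highpass_order: 4
  notch_order: 2
  bandpass_order: 4
  zero_phase: true

core_fraction: [0.30, 0.70]
window_len: 250

raster:
  width: 48
  height: 48

train:
  epochs: 100
  batch_size: 16
  lambda_: 0.05     # MK-MMD weight; DANN/DeepCoral typically use 1.0
  lr: 0.01
  backbone: smallcnn
  kernel_m: 5
  kernel_spacing: 2.0
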