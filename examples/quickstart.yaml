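# Quickstart: synthesize a 12-class SSVEP dataset at 10 dB SNR, band-pass
# 8-90 Hz, crop 0.5 s windows, and cross-validate an eTRCA decoder.
seed: 0
data:
  source: synthetic
  n_classes: 12
  n_trials_per_class: 6
  n_channels: 8
  fs: 250.0
  trial_len: 1.0
  snr_db: 10.0
filter:
  enabled: true
  low_hz: 8.0
  high_hz: 90.0
  window_start_s: 0.0
  window_len_s: 0.5
model:
  decoder: etrca
  n_bands: 1
evaluation:
  selection_overhead_s: 0.5
  max_folds: 2
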