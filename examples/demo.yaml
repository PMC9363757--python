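# End-to-end synthetic demo: two groups with planted gamma-band effects,
# gamma-band PSD+PLV features, 10-fold linear SVM.
bands: [gamma]
synth:
  groups:
    - {label: HC, n: 4}
    - {label: PD, n: 4}
  fs: 256.0
  duration_s: 30.0
  seed: 7
  power_effects:
    - {group: PD, band: gamma, channels: [Fp1, F3, Cz, Pz, O1], factor: 4.0}
  coupling_effects:
    - {group: PD, band: gamma, channels: [C3, C4, F3, F4], kappa: 50.0}
preprocess:
  low_hz: 0.5
  high_hz: 50.0
  epoch_length_s: 1.0
classify:
  mode: PSD_PLV
  band: gamma
  model: svm
  folds: 10
  seed: 7
  groups: [HC, PD]
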