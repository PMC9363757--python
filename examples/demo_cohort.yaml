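# Cohort spec for `mpeeg synth`: 4 HC + 4 PD subjects, 30 s at 256 Hz,
# standard 32-channel montage, planted gamma effects in the PD group.
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
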