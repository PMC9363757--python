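# The 32-channel montage shared by the two supported acquisition systems,
# with the Pz reconstruction rule for recordings referenced to Pz.
target_channels: [Fp1, AF3, F7, F3, FC1, FC5, T7, C3, CP1, CP5, P7, P3, Pz,
                  PO3, O1, Oz, O2, PO4, P4, P8, CP6, CP2, C4, T8, FC6, FC2,
                  F4, F8, AF4, Fp2, Fz, Cz]
imputation_rules:
  Pz: [P1, P2, CPz, POz]
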