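# mpeeg — multi-pattern resting-state EEG analysis

`mpeeg` implements an end-to-end pipeline for detecting Parkinson's disease
from resting-state EEG using two complementary feature patterns:

- **activation**: per-channel band power (PSD) in the canonical δ (1–4 Hz),
  θ (4–8), α (8–12), β (13–30) and γ (30–48 Hz) bands, one value per
  1-second epoch, computed from the DFT periodogram;
- **connectivity**: phase-locking value (PLV) for all channel pairs
  (496 pairs for the standard 32-channel montage), from Hamming-window FIR
  band-pass filtering and Hilbert-transform instantaneous phase, with
  Fisher-transform (arctanh-domain) group averaging.

On top of the features it provides group contrast maps (mean ratios with
Student's-t significance masks), a linear-SVM baseline, and a multi-scale
CNN (two parallel sub-networks — a 2-D stack with an identity-skip residual
block and a 1-D stack — over a 32×32 input assembled from the PSD+PLV
feature vector), all evaluated with stratified 10-fold cross-validation
(accuracy / sensitivity / specificity / ROC-AUC).

A first-class **synthetic cohort generator** plants group-conditional band
power (multiplicative factors) and phase coupling (von-Mises concentration
κ) on top of 1/f background noise, so every stage is testable offline.

The CNN is implemented as a small numpy layer library with manual
backpropagation (verified by numeric gradient checks) so the package has no
deep-learning framework dependency; EDF/BDF I/O is likewise implemented
directly against the published format, and EEGLAB `.set` files are read via
`scipy.io`.

## CLI

All stages are subcommands of one entry point (`mpeeg --help`):

```sh
# one-command synthetic demo: cohort -> preprocess -> features -> contrast -> SVM
mpeeg run --config examples/demo.yaml --out out/

# or stage by stage
mpeeg synth --spec examples/demo_cohort.yaml --out raw/        # EDF + manifest.csv
mpeeg preprocess --input raw/ --format edf --band 0.5 50 \
    --montage examples/montage32.yaml --epoch 1.0 --out pre/   # epoched HDF5
mpeeg features --in pre/ --bands all --out feats/              # CSV feature table
mpeeg contrast --in pre/ --mode plv --band gamma --groups HC PD --out contrast.png
mpeeg classify --features pre/ --mode psd+plv --band gamma \
    --groups HC PD --model svm --folds 10 --seed 7 --out report.json
mpeeg train-mcnn --features pre/ --band gamma --groups HC,PD \
    --folds 10 --seed 7 --out mcnn_report.json
```

Reports are JSON (per-fold confusions, aggregate percent metrics, ROC
points, AUC, seeds); ROC points are also written as CSV next to the
classify report.

## Layout

| Module | Contents |
| --- | --- |
| `mpeeg.core` | `Recording`/`EpochedRecording` model, EDF/BDF/EEGLAB readers and writers, band-pass, montage harmonization (incl. Pz imputation), truncation, epoching, HDF5 container |
| `mpeeg.features` | band definitions, periodogram band power, FIR band-pass, Hilbert phase, PLV, Fisher averaging, CSV feature store |
| `mpeeg.contrast` | group-mean ratio + t-test contrast maps, topographic/matrix rendering, Benjamini–Hochberg option |
| `mpeeg.classify` | feature assembly (PSD / PLV / PSD+PLV), leakage-safe z-scoring, stratified k-fold CV driver, linear SVM, metrics, ROC/AUC |
| `mpeeg.mcnn` | numpy layer library, multi-scale CNN, LeNet-5 baseline, SGD training with inverse-time lr decay, CV |
| `mpeeg.synthetic` | cohort generator with planted power/coupling effects, planted-vs-recovered effect report |
| `mpeeg.cli` / `mpeeg.pipeline` | subcommands and the config-driven pipeline |
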