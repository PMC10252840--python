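# stresspipe

A DWT-based hybrid deep-learning pipeline for binary stress detection from
multichannel EEG, with a seeded synthetic EEG generator so the whole pipeline
is testable without any external download.

The pipeline: multichannel recordings in a plain-text dialect (whitespace
table, 14 electrode columns, 128 Hz) are decomposed per channel with a
4-level Daubechies-4 DWT, denoised by FDR (Benjamini–Hochberg) hard
thresholding, cut into labelled univariate windows, and classified by one of
six hybrid CNN/recurrent architectures (CBGG, CBLL, CBRR, CNN-RNN, CNN-LSTM,
CNN-GRU) trained with Adam on binary cross-entropy. Evaluation covers
confusion-matrix metrics with likelihood ratios, ROC/AUC, convergence
traces, and stratified 10-fold cross-validation.

Everything numerical is implemented on NumPy/SciPy: the orthonormal DWT
(periodized boundaries, perfect reconstruction to ~1e-15, exact coefficient
energy conservation) and the full sequence-model engine (BPTT for simple
RNN / LSTM / GRU in both bias variants / BiLSTM, verified against
finite-difference gradients). No deep-learning framework is required.

## CLI

```sh
# write a synthetic dataset: sub01_lo.txt ... sub48_hi.txt + ratings.txt
stresspipe simulate --out data/ --subjects 48 --seed 1

# look at one recording
stresspipe inspect data/sub07_hi.txt

# per-band reconstructions + band-energy summary for one channel
stresspipe decompose data/sub07_hi.txt --channel 0 --out dec/sub07

# train one architecture end to end (simulates data unless --data is given)
stresspipe train --model CBGG --data data/ --epochs 20 --batch 50 --seed 1 --out runs/cbgg

# recompute test metrics from a finished run directory
stresspipe evaluate runs/cbgg

# stratified k-fold cross-validation on synthetic data
stresspipe cv --model CBGG --k 10 --seed 1 --subjects 8 --epochs 10

# full pipeline from a YAML config
stresspipe run --config config.yaml --seed 1 --out runs/full
```

A run directory is self-describing: `config.yaml`, window manifest,
parameter-count report, fitted model, convergence trace, confusion matrix,
metrics table and ROC points as columnar text.

## Package layout

| module | role |
| --- | --- |
| `stresspipe.synthetic` | seeded STEW-dialect EEG generator with class-dependent band power |
| `stresspipe.signal_io` | dialect reader/validator, burden bands, binary labelling |
| `stresspipe.wavelet` | db4 multilevel DWT, MAD noise scale, FDR hard thresholding, band reconstruction |
| `stresspipe.dataset` | window assembly, 70/30/30 split plans, stratified k-fold plans |
| `stresspipe.nn` | NumPy layer engine: pointwise conv, RNN/LSTM/GRU/BiLSTM, dropout, dense, Adam |
| `stresspipe.models` | the six architectures: build, closed-form parameter counting, train, predict |
| `stresspipe.evaluation` | metrics, ROC/AUC, cross-validation, report export |
| `stresspipe.cli` | `stresspipe` command group and the `run_pipeline` orchestrator |
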