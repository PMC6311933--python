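# m6awin

Detection of m6A-containing RNA sequence windows with a CNN+BLSTM
classifier, plus the analyses needed to characterize what the model
learned: filter-to-PWM motif extraction, gradient saliency maps,
specificity-calibrated confidence tiers, and 3'UTR position profiling.
A synthetic-data module generates miCLIP-like transcripts with planted
DRACH-motif sites so the whole pipeline is testable offline.

The neural network (convolutions, batch norm, bidirectional LSTM, Adam,
reverse-mode autodiff) is implemented on NumPy in `m6awin.autograd` —
no GPU framework required.  It is desk-scale by design.

## Pipeline

1. **simulate** — random transcripts; motif instances (default `GGACU`)
   planted at recorded single-base sites (the A of the DRACH core);
   matched motif-free background; transcript-structure table and truth
   JSON.
2. **build-dataset** — merge clustered sites (single-linkage within
   50 nt, lower-median representative), cut 101-nt positive windows with
   the site at a uniformly random in-window position (clamped at
   transcript termini), search the closest site-free negative window at
   offsets `100 + 10k` (k < 100) up/downstream, split 80/20 with 1/8 of
   the training part as validation.
3. **train / gridsearch** — one-hot input (A,C,G,U channels; N = zero
   column) padded by half the first filter width; conv(256, w10) → BN →
   ReLU → dropout → conv(128, w5) → BN → ReLU → dropout → BLSTM → FC →
   sigmoid; BCE + Adam, early stopping on validation loss; stratified
   5-fold CV grid search.
4. **predict / evaluate / calibrate** — accuracy, sensitivity,
   specificity, F1, MCC, ROC/PR with AUROC/AUPR; confidence tiers
   (moderate/high/very-high) as the smallest thresholds reaching
   90/95/99% specificity on validation negatives.
5. **motifs / saliency** — per-filter activation-weighted PWMs (MEME
   minimal format output, TOMTOM-ready); per-nucleotide saliency
   |∂logit/∂x| ⊙ x, with most-salient-nucleotide and site-percentile
   analyses.
6. **profile** — tile transcripts into 101-nt bins, tier each bin, and
   profile confident bins' normalized distance to the 3'UTR start.

All coordinates are 0-based half-open.  Inputs are transcript-oriented
(5'→3'); T is converted to U on input.

## CLI

```sh
m6awin simulate --n 200 --seed 7 --out sim/
m6awin build-dataset --fasta sim/transcripts.fa --sites sim/sites.tsv \
    --seed 7 --out ds/
m6awin train --dataset ds/ --config config.yaml --out model.ckpt
m6awin predict --model model.ckpt --fasta ds/val.fa --out val_preds.tsv
m6awin calibrate --preds val_preds.tsv --labels ds/val.windows.tsv \
    --out thresholds.json
m6awin predict --model model.ckpt --fasta ds/test.fa \
    --thresholds thresholds.json --out preds.tsv
m6awin evaluate --preds preds.tsv --labels ds/test.windows.tsv \
    --out metrics.json --curves-out curves/
m6awin motifs --model model.ckpt --fasta ds/train.fa --out motifs.meme
m6awin saliency --model model.ckpt --fasta windows.fa --out saliency.tsv
m6awin profile --model model.ckpt --fasta sim/transcripts.fa \
    --structure sim/structure.tsv --thresholds thresholds.json \
    --out profile.tsv --hist-out hist.tsv
```

`config.yaml` holds flat `ModelConfig` overrides, e.g.:

```yaml
filter_counts: [16, 8]
blstm_units: 16
batch_size: 32
learning_rate: 0.01
blstm_reduction: mean   # "final" (default) needs far more data/updates
dropout_rate: 0.25
max_epochs: 20
```

At desk scale (hundreds of windows) use `blstm_reduction: mean` — the
default final-state readout learns far too slowly with only a few
hundred optimizer updates.

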