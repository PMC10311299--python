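# tsapred

Prediction and interpretation of binned nuclear-body proximity signals
(TSA-seq enrichment) from DNA sequence and epigenomic features.

The package implements a full desk-scale pipeline:

- **preprocess** — non-overlapping genomic bins (default 25 kb) with an
  exclude-list validity mask; canonical (strand-merged) k-mer frequencies for
  k = 5 and 6 reduced to 20 PCA components; peak-occupancy features for
  ATAC + 8 histone marks normalized by their genome-wide means; target signals
  quantile-clipped, scaled to [−1, 1] and smoothed with a Hanning window of
  size 21.
- **model** — a multi-modal transformer: separate dense-ReLU encoders for the
  sequence and epigenomic inputs, concatenated and passed through a
  post-norm transformer encoder stack with multi-head scaled-dot-product
  attention and Transformer-XL-style relative positional terms, ending in a
  Tanh prediction head. An optional domain classifier sits behind a
  gradient-reversal layer for adversarial cross-cell-type training. The
  network runs on a small in-repo reverse-mode autodiff engine
  (`tsapred.autodiff`) — no deep-learning framework required.
- **train_eval** — odd/even-autosome chromosome splits with odd-chromosome
  cross-validation folds, inverse-sqrt learning-rate warmup/decay, Adam,
  masked-MSE training with argmin-validation checkpointing, per-chromosome
  MSE/Pearson evaluation, and baselines (gradient tree boosting, DNN, CNN,
  dilated CNN, cross-cell-type signal averaging).
- **interpret** — integrated gradients against a zero baseline (midpoint
  Riemann path sum), genome-wide per-feature importance matrices, percentage
  contribution summaries, k-means pattern clustering with silhouette model
  selection, annotation enrichment (log2 fold change vs a sampled
  background), importance deciles, and boundary meta-profiles.
- **synthetic** — a fully seeded generator producing a shared multi-chromosome
  genome with a latent spatial-state segmentation, per-cell-type peak tracks,
  and target signals that are a *known* Tanh-linear function of the
  engineered features (with neighboring-bin terms for context dependence), so
  every stage is testable offline.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (feature-engineering
exactness, attention/IG oracles, gradient-reversal behavior, end-to-end
synthetic recovery, cross-cell-type transfer, interpretation recovery,
protocol integrity). The full suite trains several small models and takes
roughly 10 minutes on one CPU.

## CLI

```bash
tsapred simulate   --config cfg.yaml --out data/
tsapred preprocess --genome data/genome.fa --chrom-sizes data/genome.chrom.sizes \
                   --peaks-dir data/peaks/CT1 --signal data/signal/CT1.SON.bedGraph \
                   --cell-type CT1 --body SON --out feats/CT1_SON
tsapred train      --features feats/CT1_SON --config cfg.yaml --out run/
tsapred cross-train --features feats/CT1_LMNB --features feats/CT2_LMNB \
                   --features feats/CT3_LMNB --held-out CT3 --out run_cross/
tsapred predict    --model run/model.npz --features feats/CT1_SON --out preds/
tsapred evaluate   --predictions preds/predictions.bedGraph \
                   --features feats/CT1_SON --out eval/
tsapred interpret  --model run/model.npz --features feats/CT1_SON --out interp/
```

Every stage writes a `manifest.yaml` (config snapshot, seeds, input digests);
`--resume` skips a stage whose manifest and input digests are unchanged.
Formats: FASTA, chrom.sizes, BED3/6/narrowPeak, bedGraph, TSV/JSON/YAML
(bigWig input is not supported in this build — convert to bedGraph first).

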