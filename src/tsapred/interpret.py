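"""Post-hoc model interpretation: integrated gradients, genome-wide importance
aggregation, pattern clustering, and annotation enrichment / boundary
profiles."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .autodiff import Tensor
from .model import SpatialModel
from .train import CellDataset, WindowSampler

__all__ = [
    "integrated_gradients",
    "completeness_error",
    "ImportanceMatrix",
    "genome_importance",
    "contribution_summary",
    "PatternClustering",
    "cluster_patterns",
    "annotation_enrichment",
    "importance_deciles",
    "boundary_profile",
]


# ------------------------------------------------------- integrated gradients
def integrated_gradients(model: SpatialModel, seq_x: np.ndarray, epi_x: np.ndarray,
                         key_mask: np.ndarray, steps: int = 50):
    """Path-integral attribution against the all-zeros baseline.

    attribution_j = x_j * mean over midpoint path samples a of dF/dx_j at a*x,
    where F is the center-bin prediction. Inputs are a single window
    (L, seq_dim) / (L, epi_dim). Returns (seq_attr, epi_attr) of the input
    shapes.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    model.eval()
    alphas = (np.arange(steps) + 0.5) / steps
    sx = Tensor(alphas[:, None, None] * seq_x[None], requires_grad=True)
    ex = Tensor(alphas[:, None, None] * epi_x[None], requires_grad=True)
    km = np.broadcast_to(np.asarray(key_mask, dtype=bool), (steps, len(key_mask)))
    preds, _, _ = model.forward_tensors(sx, ex, km)
    preds.sum().backward()
    if not (np.isfinite(sx.grad).all() and np.isfinite(ex.grad).all()):
        raise FloatingPointError("non-finite gradients in integrated gradients")
    return seq_x * sx.grad.mean(axis=0), epi_x * ex.grad.mean(axis=0)


def completeness_error(model: SpatialModel, seq_x, epi_x, key_mask,
                       steps: int = 256) -> float:
    """Relative error of the completeness identity sum(attr) = F(x) - F(0)."""
    sa, ea = integrated_gradients(model, seq_x, epi_x, key_mask, steps=steps)
    fx = float(model.predict(seq_x[None], epi_x[None], key_mask[None])[0])
    f0 = float(model.predict(np.zeros_like(seq_x)[None],
                             np.zeros_like(epi_x)[None], key_mask[None])[0])
    total = sa.sum() + ea.sum()
    denom = max(abs(fx - f0), 1e-12)
    return abs(total - (fx - f0)) / denom


# --------------------------------------------------------- genome-wide matrix
@dataclass
class ImportanceMatrix:
    """Per-bin absolute attributions: one column per epigenomic track plus an
    aggregated sequence column (sum of absolute attributions over the
    sequence dimensions of the center bin). ``context`` holds the absolute
    attribution mass assigned to non-center positions (diagnostic)."""

    bin_index: np.ndarray            # global bin indices (valid centers)
    values: np.ndarray               # (n, n_tracks + 1), all >= 0
    feature_names: tuple
    context: np.ndarray | None = None
    steps: int = 50
    cell_type: str = ""
    body: str = ""


def genome_importance(model: SpatialModel, ds: CellDataset, chroms,
                      steps: int = 50, track_names=None) -> ImportanceMatrix:
    """Integrated-gradients importance for every center bin on ``chroms``."""
    sampler = WindowSampler(ds, model.config.window, chroms)
    W = model.config.window
    tracks = tuple(track_names) if track_names is not None else tuple(
        f"track{i}" for i in range(ds.epi.shape[1]))
    names = tracks + ("sequence",)
    rows, idxs, ctx = [], [], []
    for j in range(len(sampler)):
        seq, epi, km, _, _ = sampler.batch([j])
        sa, ea = integrated_gradients(model, seq[0], epi[0], km[0], steps=steps)
        sa, ea = np.abs(sa), np.abs(ea)
        rows.append(np.concatenate([ea[W], [sa[W].sum()]]))
        ctx.append(sa.sum() + ea.sum() - sa[W].sum() - ea[W].sum())
        chrom, i = sampler.centers[j]
        idxs.append(ds.bins.chrom_slice(chrom).start + i)
    return ImportanceMatrix(
        bin_index=np.asarray(idxs, dtype=np.int64),
        values=np.asarray(rows),
        feature_names=names,
        context=np.asarray(ctx),
        steps=steps,
        cell_type=ds.cell_type,
    )


def contribution_summary(imp: ImportanceMatrix) -> pd.Series:
    """Mean importance per feature over bins, normalized to sum to 100%."""
    mean = imp.values.mean(axis=0)
    total = mean.sum()
    if total == 0:
        return pd.Series(np.zeros(len(mean)), index=list(imp.feature_names))
    return pd.Series(100.0 * mean / total, index=list(imp.feature_names))


# ---------------------------------------------------------------- clustering
@dataclass
class PatternClustering:
    k: int
    labels: np.ndarray               # 1..k, aligned to kept bins
    bin_index: np.ndarray
    centroids: np.ndarray
    silhouettes: dict                # candidate k -> mean silhouette
    seed: int


def cluster_patterns(imp: ImportanceMatrix, k_range=range(2, 11), seed: int = 0,
                     n_restarts: int = 10, max_silhouette_n: int = 20_000,
                     normalization: str = "proportion") -> PatternClustering:
    """K-means over per-bin normalized importance vectors; k chosen by mean
    silhouette."""
    k_range = list(k_range)
    if min(k_range) < 2 or max(k_range) > 15:
        raise ValueError("k_range must lie within [2, 15]")
    X = imp.values.astype(np.float64)
    row_sum = X.sum(axis=1)
    keep = row_sum > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} all-zero importance rows excluded")
    X = X[keep]
    if normalization == "proportion":
        X = X / X.sum(axis=1, keepdims=True)
    elif normalization == "zscore":
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if len(X) < max(k_range):
        raise ValueError("fewer bins than the largest candidate k")
    rng = np.random.default_rng(seed)
    sub = (rng.choice(len(X), size=max_silhouette_n, replace=False)
           if len(X) > max_silhouette_n else np.arange(len(X)))
    sil, fits = {}, {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(X)
        fits[k] = (km, labels)
        if len(np.unique(labels[sub])) < 2:
            sil[k] = -1.0
        else:
            sil[k] = float(silhouette_score(X[sub], labels[sub]))
    best = max(sil, key=lambda k: sil[k])
    km, labels = fits[best]
    return PatternClustering(
        k=best,
        labels=labels + 1,
        bin_index=imp.bin_index[keep],
        centroids=km.cluster_centers_.copy(),
        silhouettes=sil,
        seed=seed,
    )


# ----------------------------------------------------------------- analyses
def annotation_enrichment(groups: np.ndarray, annotation: np.ndarray,
                          valid: np.ndarray | None = None,
                          background_seed: int = 0,
                          background_size: int | None = None) -> pd.DataFrame:
    """log2 fold change of category frequencies in each group vs a randomly
    sampled background of valid bins.

    ``groups`` may contain None/NaN for unassigned bins. Pseudocount
    eps = 1 / background_size.
    """
    groups = np.asarray(groups, dtype=object)
    annotation = np.asarray(annotation, dtype=object)
    if len(groups) != len(annotation):
        raise ValueError("groups and annotation must share the bin frame")
    if valid is None:
        valid = np.ones(len(groups), dtype=bool)
    assigned = np.array([g is not None and g == g for g in groups])
    if background_size is None:
        background_size = int((assigned & valid).sum())
    eps = 1.0 / background_size
    rng = np.random.default_rng(background_seed)
    pool = np.flatnonzero(valid)
    bg = rng.choice(pool, size=background_size, replace=True)
    cats = sorted({c for c in annotation[valid]}, key=str)
    bg_freq = {c: np.mean(annotation[bg] == c) for c in cats}
    rows = {}
    for g in sorted({x for x in groups[assigned]}, key=str):
        sel = (groups == g) & valid
        n = int(sel.sum())
        if n == 0:
            rows[g] = {c: np.nan for c in cats}
            continue
        rows[g] = {
            c: np.log2((np.mean(annotation[sel] == c) + eps) / (bg_freq[c] + eps))
            for c in cats
        }
    return pd.DataFrame.from_dict(rows, orient="index")[cats]


def importance_deciles(values: np.ndarray) -> np.ndarray:
    """Rank-based split into 10 equal-size groups; 10 = highest importance.

    Ties broken by position; group sizes differ by at most 1.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if n < 10:
        raise ValueError("need at least 10 values")
    order = np.argsort(values, kind="stable")
    out = np.empty(n, dtype=np.int64)
    for d, chunk in enumerate(np.array_split(order, 10)):
        out[chunk] = d + 1
    return out


def boundary_profile(values: np.ndarray, mask: np.ndarray, boundaries,
                     flank_bins: int, n_bins: int | None = None) -> np.ndarray:
    """Mean importance vs signed bin offset around boundaries.

    ``boundaries`` is a sequence of (bin_index, direction) pairs where
    direction = +1 means the domain extends toward increasing indices;
    positive offsets point into the domain. Returns an array of length
    2*flank_bins + 1 (offset -flank .. +flank); masked or out-of-range
    positions are skipped.
    """
    if flank_bins < 1:
        raise ValueError("flank_bins must be >= 1")
    n = n_bins if n_bins is not None else len(values)
    acc = np.zeros(2 * flank_bins + 1)
    cnt = np.zeros(2 * flank_bins + 1)
    for b, direction in boundaries:
        if not 0 <= b < n:
            warnings.warn(f"boundary at bin {b} outside the bin frame; skipped")
            continue
        for off in range(-flank_bins, flank_bins + 1):
            i = b + off * int(direction)
            if 0 <= i < n and mask[i]:
                acc[off + flank_bins] += values[i]
                cnt[off + flank_bins] += 1
    out = np.full(2 * flank_bins + 1, np.nan)
    ok = cnt > 0
    out[ok] = acc[ok] / cnt[ok]
    return out
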