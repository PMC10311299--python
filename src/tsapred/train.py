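"""Training loop, chromosome-parity splits, metrics, and baseline models."""

from __future__ import annotations

import copy
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .autodiff import Tensor, log_softmax
from .model import ModelConfig, SpatialModel
from .preprocess import BinTable, TargetTrack

__all__ = [
    "SplitScheme",
    "TrainConfig",
    "EvalReport",
    "CellDataset",
    "WindowSampler",
    "autosome_number",
    "make_splits",
    "n_folds",
    "lr_schedule",
    "Adam",
    "train",
    "evaluate",
    "average_baseline",
    "predict_track",
    "cross_cell_type_protocol",
    "DNNBaseline",
    "ConvBaseline",
    "GTBBaseline",
    "make_baseline",
]


# ------------------------------------------------------------------- splits
@dataclass
class SplitScheme:
    train_chroms: tuple
    val_chroms: tuple
    test_chroms: tuple

    def all_chroms(self):
        return self.train_chroms + self.val_chroms + self.test_chroms


def autosome_number(chrom: str) -> int | None:
    m = re.fullmatch(r"(?:chr)?(\d+)", chrom)
    return int(m.group(1)) if m else None


def _autosomes(chroms):
    out = []
    for c in chroms:
        n = autosome_number(c)
        if n is None:
            warnings.warn(f"non-autosomal chromosome {c!r} excluded from splits")
        else:
            out.append((n, c))
    return out


def n_folds(bins: BinTable) -> int:
    return sum(1 for n, _ in _autosomes(bins.chrom_order) if n % 2 == 1)


def make_splits(bins: BinTable, fold: int = 0) -> SplitScheme:
    """Even autosomes -> test; the fold-th odd autosome -> validation;
    remaining odd autosomes -> train."""
    autos = _autosomes(bins.chrom_order)
    odd = [c for n, c in autos if n % 2 == 1]
    even = [c for n, c in autos if n % 2 == 0]
    if not odd:
        raise ValueError("no odd-numbered autosomes available for training")
    if not 0 <= fold < len(odd):
        raise ValueError(f"fold {fold} out of range for {len(odd)} odd autosomes")
    val = (odd[fold],)
    trainc = tuple(c for c in odd if c != odd[fold])
    if not trainc:  # degenerate: a single odd autosome
        trainc = val
    return SplitScheme(train_chroms=trainc, val_chroms=val, test_chroms=tuple(even))


# ----------------------------------------------------------------- schedule
def lr_schedule(step: int, d_model: int, warmup_steps: int, scale: float = 1.0) -> float:
    """Inverse-sqrt schedule with linear warmup."""
    if step < 1:
        raise ValueError("step must be >= 1")
    return scale * d_model ** -0.5 * min(step ** -0.5, step * warmup_steps ** -1.5)


# --------------------------------------------------------------------- data
@dataclass
class CellDataset:
    """Feature/target matrices of one cell type on a shared bin frame."""

    bins: BinTable
    seq: np.ndarray                 # (n_bins, seq_dim), NaN on invalid bins
    epi: np.ndarray                 # (n_bins, epi_dim)
    target: TargetTrack
    cell_type: str = ""


def standardize(ds: CellDataset) -> CellDataset:
    """Z-score every feature column over valid bins (per dataset).

    Puts the low-magnitude sequence components and the occupancy tracks
    (which sit near 1 after normalization) on a common scale; the network's
    zero input / attribution baseline then corresponds to the genome-wide
    mean feature vector.
    """
    valid = ds.bins.valid

    def z(x):
        mu = np.nanmean(x[valid], axis=0)
        sd = np.nanstd(x[valid], axis=0)
        return (x - mu) / np.where(sd > 0, sd, 1.0)

    return CellDataset(bins=ds.bins, seq=z(ds.seq), epi=z(ds.epi),
                       target=ds.target, cell_type=ds.cell_type)


class WindowSampler:
    """Builds +/-W-bin context windows around center bins of given chromosomes.

    Positions beyond chromosome ends are zero-padded and masked; invalid
    interior bins are masked as keys but retained as positions.
    """

    def __init__(self, ds: CellDataset, window: int, chroms):
        self.W = window
        self.L = 2 * window + 1
        self.centers = []            # (chrom, local index)
        self._seq = {}
        self._epi = {}
        self._mask = {}
        self._y = {}
        self._ymask = {}
        W = window
        for chrom in chroms:
            sl = ds.bins.chrom_slice(chrom)
            n = sl.stop - sl.start
            seq = np.nan_to_num(ds.seq[sl], nan=0.0)
            epi = np.nan_to_num(ds.epi[sl], nan=0.0)
            valid = ds.bins.valid[sl]
            y = np.nan_to_num(ds.target.values[sl], nan=0.0)
            ym = ds.target.mask[sl]
            pad = ((W, W), (0, 0))
            self._seq[chrom] = np.pad(seq * valid[:, None], pad)
            self._epi[chrom] = np.pad(epi * valid[:, None], pad)
            self._mask[chrom] = np.pad(valid, (W, W))
            self._y[chrom] = np.pad(y, (W, W))
            self._ymask[chrom] = np.pad(ym, (W, W))
            for i in range(n):
                if valid[i] and ym[i]:
                    self.centers.append((chrom, i))

    def __len__(self):
        return len(self.centers)

    def batch(self, idxs):
        """Window arrays for the given center indices.

        Returns (seq_x, epi_x, key_mask, y, y_mask) with shapes
        (B,L,ds), (B,L,de), (B,L), (B,L), (B,L).
        """
        B, L = len(idxs), self.L
        seq = np.empty((B, L, next(iter(self._seq.values())).shape[1]))
        epi = np.empty((B, L, next(iter(self._epi.values())).shape[1]))
        km = np.empty((B, L), dtype=bool)
        y = np.empty((B, L))
        ym = np.empty((B, L), dtype=bool)
        for b, j in enumerate(idxs):
            chrom, i = self.centers[j]
            sl = slice(i, i + L)
            seq[b] = self._seq[chrom][sl]
            epi[b] = self._epi[chrom][sl]
            km[b] = self._mask[chrom][sl]
            y[b] = self._y[chrom][sl]
            ym[b] = self._ymask[chrom][sl]
        return seq, epi, km, y, ym


# ---------------------------------------------------------------- optimizer
class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.98), eps: float = 1e-9,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()


# ------------------------------------------------------------- train config
@dataclass
class TrainConfig:
    batch_size: int = 64
    max_epochs: int = 50
    patience: int = 10
    warmup_steps: int = 100
    lr_scale: float = 1.0
    weight_decay: float = 0.0
    feature_noise: float = 0.0      # sd of Gaussian input jitter (train only)
    seed: int = 0
    domain_adaptation: bool = False
    grl_lambda_max: float = 1.0
    fold: int = 0

    def __post_init__(self):
        if self.warmup_steps < 1:
            raise ValueError("warmup_steps must be >= 1")


def grl_lambda(progress: float, lam_max: float = 1.0) -> float:
    """Schedule lambda(p) = lam_max * (2 / (1 + exp(-10 p)) - 1)."""
    return lam_max * (2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0)


def _masked_mse_loss(preds, y, ym, W, mode):
    """Masked MSE as an autodiff scalar. Returns None if nothing unmasked."""
    if mode == "center":
        sel = ym[:, W]
        if not sel.any():
            return None
        diff = preds[np.flatnonzero(sel)] - Tensor(y[sel, W])
        return (diff * diff).mean()
    m = ym.astype(np.float64)
    tot = m.sum()
    if tot == 0:
        return None
    diff = (preds - Tensor(y)) * Tensor(m)
    return (diff * diff).sum() * (1.0 / tot)


def _domain_ce(dom_logits, labels):
    lsm = log_softmax(dom_logits)
    B = len(labels)
    return -lsm[np.arange(B), labels].mean()


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    val_loss: list = field(default_factory=list)
    best_epoch: int = -1


def train(model: SpatialModel, datasets: dict, split: SplitScheme,
          config: TrainConfig) -> History:
    """Fit ``model`` by masked MSE (+ adversarial domain loss when enabled).

    ``datasets`` maps cell-type name -> CellDataset; all must share feature
    dimensions. The checkpoint with minimum validation loss is restored into
    ``model`` before returning.
    """
    cts = sorted(datasets)
    if model.config.domain_head and len(cts) < 2:
        raise ValueError("domain adaptation requires >= 2 training cell types")
    W = model.config.window
    mode = model.config.prediction_mode
    train_samplers = {ct: WindowSampler(datasets[ct], W, split.train_chroms) for ct in cts}
    val_samplers = {ct: WindowSampler(datasets[ct], W, split.val_chroms) for ct in cts}
    if sum(len(s) for s in val_samplers.values()) == 0:
        raise ValueError("validation set is empty")
    pool = [(ct, i) for ct in cts for i in range(len(train_samplers[ct]))]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.params(), lr=0.0, weight_decay=config.weight_decay)
    hist = History()
    best = None
    best_val = np.inf
    step = 0
    total_steps = max(1, config.max_epochs * (len(pool) // config.batch_size + 1))
    since_best = 0
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(pool))
        model.train()
        ep_loss, ep_n = 0.0, 0
        for lo in range(0, len(order), config.batch_size):
            sel = [pool[k] for k in order[lo:lo + config.batch_size]]
            step += 1
            opt.lr = lr_schedule(step, model.config.d_model, config.warmup_steps,
                                 config.lr_scale)
            lam = grl_lambda(step / total_steps, config.grl_lambda_max) \
                if (config.domain_adaptation and model.config.domain_head) else 0.0
            model.zero_grad()
            batch_loss = None
            # group by cell type so each forward gets a homogeneous domain label
            for ct_idx, ct in enumerate(cts):
                idxs = [i for c, i in sel if c == ct]
                if not idxs:
                    continue
                seq, epi, km, y, ym = train_samplers[ct].batch(idxs)
                if config.feature_noise > 0:
                    seq = seq + rng.normal(0, config.feature_noise, seq.shape) * km[..., None]
                    epi = epi + rng.normal(0, config.feature_noise, epi.shape) * km[..., None]
                preds, dom, _ = model.forward_tensors(
                    Tensor(seq), Tensor(epi), km, grl_lambda=lam)
                loss = _masked_mse_loss(preds, y, ym, W, mode)
                if loss is None:
                    continue
                loss = loss * (len(idxs) / len(sel))
                if dom is not None and config.domain_adaptation:
                    labels = np.full(len(idxs), ct_idx)
                    loss = loss + _domain_ce(dom, labels) * (
                        model.config.domain_weight * len(idxs) / len(sel))
                batch_loss = loss if batch_loss is None else batch_loss + loss
            if batch_loss is None:
                continue
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(f"non-finite loss at step {step}")
            batch_loss.backward()
            opt.step()
            ep_loss += batch_loss.item() * len(sel)
            ep_n += len(sel)
        hist.train_loss.append(ep_loss / max(ep_n, 1))

        model.eval()
        vl, vn = 0.0, 0
        for ct in cts:
            s = val_samplers[ct]
            for lo in range(0, len(s), 256):
                idxs = list(range(lo, min(lo + 256, len(s))))
                seq, epi, km, y, ym = s.batch(idxs)
                preds, _, _ = model.forward_tensors(Tensor(seq), Tensor(epi), km)
                loss = _masked_mse_loss(preds, y, ym, W, mode)
                if loss is not None:
                    n = int(ym[:, W].sum()) if mode == "center" else int(ym.sum())
                    vl += loss.item() * n
                    vn += n
        val = vl / max(vn, 1)
        hist.val_loss.append(val)
        if val < best_val:
            best_val = val
            best = [p.data.copy() for p in model.params()]
            hist.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if best is not None:
        for p, b in zip(model.params(), best):
            p.data = b
    model.eval()
    return hist


# ------------------------------------------------------------------ predict
def predict_track(model: SpatialModel, ds: CellDataset, chroms,
                  batch_size: int = 256) -> np.ndarray:
    """Genome-wide per-bin predictions (NaN where no prediction)."""
    out = np.full(ds.bins.n_bins, np.nan)
    sampler = WindowSampler(ds, model.config.window, chroms)
    W = model.config.window
    for lo in range(0, len(sampler), batch_size):
        idxs = list(range(lo, min(lo + batch_size, len(sampler))))
        seq, epi, km, _, _ = sampler.batch(idxs)
        preds = model.predict(seq, epi, km)
        if model.config.prediction_mode != "center":
            preds = preds[:, W]
        for b, j in enumerate(idxs):
            chrom, i = sampler.centers[j]
            out[ds.bins.chrom_slice(chrom).start + i] = preds[b]
    return out


# ------------------------------------------------------------------ metrics
@dataclass
class EvalReport:
    per_chrom: dict                 # chrom -> {"mse","pcc","n_bins"}
    median_mse: float
    median_pcc: float
    model_id: str = ""
    protocol: str = "single"


def evaluate(predictions: np.ndarray, target: TargetTrack, bins: BinTable,
             chroms=None, model_id: str = "", protocol: str = "single") -> EvalReport:
    """Per-chromosome MSE and Pearson correlation over valid target bins."""
    chroms = list(chroms) if chroms is not None else list(bins.chrom_order)
    per = {}
    for chrom in chroms:
        sl = bins.chrom_slice(chrom)
        m = target.mask[sl] & np.isfinite(predictions[sl])
        p, t = predictions[sl][m], target.values[sl][m]
        entry = {"n_bins": int(m.sum()), "mse": float(np.mean((p - t) ** 2)) if m.any() else np.nan}
        if m.sum() >= 2 and np.std(t) > 0 and np.std(p) > 0:
            entry["pcc"] = float(stats.pearsonr(p, t).statistic)
        else:
            entry["pcc"] = np.nan
        per[chrom] = entry
    mses = [v["mse"] for v in per.values() if np.isfinite(v["mse"])]
    pccs = [v["pcc"] for v in per.values() if np.isfinite(v["pcc"])]
    return EvalReport(
        per_chrom=per,
        median_mse=float(np.median(mses)) if mses else np.nan,
        median_pcc=float(np.median(pccs)) if pccs else np.nan,
        model_id=model_id,
        protocol=protocol,
    )


def average_baseline(tracks) -> TargetTrack:
    """Per-bin mean of training-cell-type tracks over cell types where the
    bin is valid; masked only where invalid in all."""
    tracks = list(tracks)
    if not tracks:
        raise ValueError("need at least one track")
    vals = np.stack([np.where(t.mask, t.values, 0.0) for t in tracks])
    masks = np.stack([t.mask for t in tracks])
    cnt = masks.sum(axis=0)
    out = np.full(vals.shape[1], np.nan)
    ok = cnt > 0
    out[ok] = vals.sum(axis=0)[ok] / cnt[ok]
    return TargetTrack(values=out, mask=ok, cell_type="average", body=tracks[0].body,
                       clip_bounds=tracks[0].clip_bounds)


# ---------------------------------------------------------------- baselines
class DNNBaseline:
    """Context-free dense network on single-bin features (linear output).

    ``hidden=()`` reduces to ordinary linear regression.
    """

    def __init__(self, d_in: int, hidden=(64, 64, 64), seed: int = 0):
        from .model import Dense
        rng = np.random.default_rng(seed)
        dims = [d_in, *hidden, 1]
        self.layers = [Dense(rng, a, b) for a, b in zip(dims[:-1], dims[1:])]

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: Tensor) -> Tensor:
        for l in self.layers[:-1]:
            x = l(x).relu()
        return self.layers[-1](x)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 300,
            lr: float = 1e-2, batch_size: int = 256, seed: int = 0):
        rng = np.random.default_rng(seed)
        opt = Adam(self.params(), lr=lr, betas=(0.9, 0.999), eps=1e-8)
        n = len(X)
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, batch_size):
                idx = order[lo:lo + batch_size]
                opt.zero_grad()
                pred = self.forward(Tensor(X[idx]))
                diff = pred.reshape(len(idx)) - Tensor(y[idx])
                loss = (diff * diff).mean()
                loss.backward()
                opt.step()
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(Tensor(X)).data.reshape(len(X))


class Conv1D:
    """1-D convolution over window positions, zero ('same') padding."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, dilation: int = 1):
        lim = np.sqrt(6.0 / (kernel * c_in + c_out))
        self.W = Tensor(rng.uniform(-lim, lim, size=(kernel, c_in, c_out)), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.kernel = kernel
        self.dilation = dilation

    def params(self):
        return [self.W, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        from .autodiff import shift1d
        out = None
        half = self.kernel // 2
        for t in range(self.kernel):
            term = shift1d(x, (t - half) * self.dilation).matmul(self.W[t])
            out = term if out is None else out + term
        return out + self.b


class ConvBaseline:
    """CNN / dilated-CNN over the same context windows as the transformer."""

    def __init__(self, d_in: int, window: int, hidden: int = 32,
                 kernel: int = 9, dilations=(1, 1, 1, 1), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.window = window
        self.kernel = kernel
        self.dilations = tuple(dilations)
        chans = [d_in] + [hidden] * len(dilations)
        self.convs = [Conv1D(rng, a, b, kernel, d)
                      for a, b, d in zip(chans[:-1], chans[1:], dilations)]
        from .model import Dense
        self.head = Dense(rng, hidden, 1)

    def params(self):
        return [p for c in self.convs for p in c.params()] + self.head.params()

    def receptive_field(self) -> int:
        return 1 + sum((self.kernel - 1) * d for d in self.dilations)

    def forward(self, x: Tensor) -> Tensor:
        for c in self.convs:
            x = c(x).relu()
        return self.head(x).tanh()

    def fit(self, sampler: WindowSampler, epochs: int = 60, lr_scale: float = 1.0,
            warmup: int = 50, batch_size: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        opt = Adam(self.params(), lr=0.0)
        n = len(sampler)
        W = sampler.W
        step = 0
        for _ in range(epochs):
            order = rng.permutation(n)
            for lo in range(0, n, batch_size):
                idxs = [int(k) for k in order[lo:lo + batch_size]]
                seq, epi, km, y, ym = sampler.batch(idxs)
                x = np.concatenate([seq, epi], axis=-1)
                step += 1
                opt.lr = lr_schedule(step, 64, warmup, lr_scale)
                opt.zero_grad()
                pred = self.forward(Tensor(x))[:, W, 0]
                sel = np.flatnonzero(ym[:, W])
                if sel.size == 0:
                    continue
                diff = pred[sel] - Tensor(y[sel, W])
                loss = (diff * diff).mean()
                loss.backward()
                opt.step()
        return self

    def predict(self, sampler: WindowSampler, batch_size: int = 256) -> np.ndarray:
        W = sampler.W
        out = np.empty(len(sampler))
        for lo in range(0, len(sampler), batch_size):
            idxs = list(range(lo, min(lo + batch_size, len(sampler))))
            seq, epi, _, _, _ = sampler.batch(idxs)
            x = np.concatenate([seq, epi], axis=-1)
            out[lo:lo + len(idxs)] = self.forward(Tensor(x)).data[:, W, 0]
        return out


class GTBBaseline:
    """Gradient tree boosting on single-bin features (external library)."""

    def __init__(self, seed: int = 0, **kwargs):
        from sklearn.ensemble import GradientBoostingRegressor
        kwargs.setdefault("n_estimators", 200)
        self.est = GradientBoostingRegressor(random_state=seed, **kwargs)

    def fit(self, X, y):
        self.est.fit(X, y)
        return self

    def predict(self, X):
        return self.est.predict(X)


def make_baseline(kind: str, d_in: int, window: int, seed: int = 0, **kwargs):
    if kind == "dnn":
        return DNNBaseline(d_in, seed=seed, **kwargs)
    if kind == "cnn":
        kwargs.setdefault("kernel", 9)
        kwargs.setdefault("dilations", (1, 1, 1, 1))
        return ConvBaseline(d_in, window, seed=seed, **kwargs)
    if kind == "dilated_cnn":
        kwargs.setdefault("kernel", 3)
        kwargs.setdefault("dilations", (1, 2, 4, 8, 16, 32))
        return ConvBaseline(d_in, window, seed=seed, **kwargs)
    if kind == "gtb":
        return GTBBaseline(seed=seed, **kwargs)
    raise ValueError(f"unknown baseline kind {kind!r}")


def fit_model(datasets: dict, split: SplitScheme, model_cfg: ModelConfig,
              train_cfg: TrainConfig, n_restarts: int = 3, refit: bool = False):
    """Train ``n_restarts`` independently initialized models and keep the one
    with the lowest validation loss (standard restart selection; the final
    checkpoint is still argmin-validation within its own history).

    With ``refit=True`` the selected restart's seed and epoch budget are
    reused to retrain from scratch on the union of training and validation
    chromosomes (the tuned-then-refit protocol; the test chromosomes are
    never touched).

    Returns (best_model, best_history).
    """
    best_model, best_hist, best_val, best_seed = None, None, np.inf, train_cfg.seed
    for r in range(n_restarts):
        model = SpatialModel(model_cfg, seed=train_cfg.seed + 1000 * r)
        cfg = copy.deepcopy(train_cfg)
        cfg.seed = train_cfg.seed + 1000 * r
        hist = train(model, datasets, split, cfg)
        val = min(hist.val_loss)
        if val < best_val:
            best_model, best_hist, best_val = model, hist, val
            best_seed = cfg.seed
    if refit and split.val_chroms and set(split.val_chroms) != set(split.train_chroms):
        epochs = best_hist.best_epoch + 1
        all_train = tuple(dict.fromkeys(split.train_chroms + split.val_chroms))
        refit_split = SplitScheme(train_chroms=all_train,
                                  val_chroms=split.val_chroms,
                                  test_chroms=split.test_chroms)
        cfg = copy.deepcopy(train_cfg)
        cfg.seed = best_seed
        cfg.max_epochs = epochs
        cfg.patience = epochs + 1
        model = SpatialModel(model_cfg, seed=best_seed)
        hist = train(model, datasets, refit_split, cfg)
        return model, hist
    return best_model, best_hist


def domain_accuracy(model: SpatialModel, datasets: dict, chroms,
                    batch_size: int = 256) -> float:
    """Accuracy of the domain classifier on windows from ``chroms``.

    Cell-type label order = sorted(datasets), matching :func:`train`.
    """
    if model.domain_clf is None:
        raise ValueError("model has no domain head")
    cts = sorted(datasets)
    correct, total = 0, 0
    model.eval()
    for label, ct in enumerate(cts):
        sampler = WindowSampler(datasets[ct], model.config.window, chroms)
        for lo in range(0, len(sampler), batch_size):
            idxs = list(range(lo, min(lo + batch_size, len(sampler))))
            seq, epi, km, _, _ = sampler.batch(idxs)
            _, dom, _ = model.forward_tensors(Tensor(seq), Tensor(epi), km)
            correct += int((np.argmax(dom.data, axis=1) == label).sum())
            total += len(idxs)
    return correct / max(total, 1)


# -------------------------------------------------------------- cross cells
def cross_cell_type_protocol(datasets: dict, held_out: str, model_cfg: ModelConfig,
                             config: TrainConfig, model_seed: int = 0):
    """Train on all non-held-out cell types with the domain head; evaluate
    on even chromosomes of the held-out cell type.

    Returns (model, report, average-baseline report, history).
    """
    if held_out not in datasets:
        raise ValueError(f"held-out cell type {held_out!r} not in datasets")
    train_sets = {ct: ds for ct, ds in datasets.items() if ct != held_out}
    if len(train_sets) < 1:
        raise ValueError("need at least one training cell type")
    cfg = copy.deepcopy(model_cfg)
    cfg.domain_head = len(train_sets) >= 2
    cfg.n_domains = len(train_sets) if cfg.domain_head else 0
    model = SpatialModel(cfg, seed=model_seed)
    any_ds = next(iter(train_sets.values()))
    split = make_splits(any_ds.bins, fold=config.fold)
    cfg2 = copy.deepcopy(config)
    cfg2.domain_adaptation = cfg.domain_head
    hist = train(model, train_sets, split, cfg2)
    ho = datasets[held_out]
    preds = predict_track(model, ho, split.test_chroms)
    report = evaluate(preds, ho.target, ho.bins, split.test_chroms,
                      model_id="transformer", protocol="cross")
    avg = average_baseline([train_sets[ct].target for ct in sorted(train_sets)])
    avg_report = evaluate(np.where(avg.mask, avg.values, np.nan), ho.target, ho.bins,
                          split.test_chroms, model_id="average", protocol="cross")
    return model, report, avg_report, hist
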