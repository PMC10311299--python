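"""The predictive network: per-modality dense encoders, a transformer encoder
stack with multi-head attention and relative positional terms, a Tanh
prediction head, and an optional domain classifier behind a gradient-reversal
layer.

Built on :mod:`tsapred.autodiff`; a forward pass in evaluation mode is
deterministic given fixed parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import (
    Tensor,
    concat,
    grad_reverse,
    layer_norm,
    masked_softmax,
    rel_gather,
)

__all__ = [
    "ModelConfig",
    "SpatialModel",
    "scaled_dot_attention",
    "sinusoidal_relative_encodings",
    "parameter_count",
]


@dataclass
class ModelConfig:
    seq_dim: int = 20
    epi_dim: int = 9
    encoder_hidden: int = 128
    encoder_out: int = 64           # per modality; d_model = 2 * encoder_out
    n_heads: int = 8
    n_layers: int = 2
    ffn_dim: int = 256
    dropout: float = 0.1
    window: int = 100               # W; context = 2W+1 bins
    prediction_mode: str = "center"  # "center" | "per-position"
    relative_position: bool = True
    domain_head: bool = False
    n_domains: int = 0
    domain_hidden: int = 32         # 0 -> linear domain classifier
    domain_weight: float = 0.1      # beta, weight of the adversarial loss

    @property
    def d_model(self) -> int:
        return 2 * self.encoder_out

    @property
    def d_k(self) -> int:
        return self.d_model // self.n_heads

    @property
    def context_len(self) -> int:
        return 2 * self.window + 1

    def validate(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.prediction_mode not in ("center", "per-position"):
            raise ValueError(f"unknown prediction_mode {self.prediction_mode!r}")
        if self.domain_head and self.n_domains < 2:
            raise ValueError("domain head requires >= 2 training cell types")
        for name in ("encoder_hidden", "encoder_out", "n_heads", "ffn_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def sinusoidal_relative_encodings(L: int, d_model: int) -> np.ndarray:
    """Fixed sinusoidal encodings for relative offsets.

    Row ``c`` encodes offset ``o = c - (L - 1)`` (so offsets run from
    ``-(L-1)`` to ``L-1``), matching the column convention of
    :func:`tsapred.autodiff.rel_gather`.
    """
    offsets = np.arange(2 * L - 1, dtype=np.float64) - (L - 1)
    i = np.arange(d_model // 2, dtype=np.float64)
    freq = 1.0 / (10000.0 ** (2.0 * i / d_model))
    ang = offsets[:, None] * freq[None, :]
    enc = np.zeros((2 * L - 1, d_model))
    enc[:, 0::2] = np.sin(ang)
    enc[:, 1::2] = np.cos(ang[:, : d_model - d_model // 2])
    return enc


def scaled_dot_attention(Q, K, V, key_mask=None):
    """softmax(Q Kᵀ / sqrt(d_k)) V with optional key masking.

    Accepts arrays or Tensors shaped (..., L, d). Returns (output, weights).
    """
    Q = Q if isinstance(Q, Tensor) else Tensor(Q)
    K = K if isinstance(K, Tensor) else Tensor(K)
    V = V if isinstance(V, Tensor) else Tensor(V)
    if Q.shape[-1] != K.shape[-1]:
        raise ValueError("Q and K must share d_k")
    d_k = Q.shape[-1]
    logits = Q.matmul(K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)) * (1.0 / np.sqrt(d_k))
    if key_mask is None:
        key_mask = np.ones(logits.shape[-1], dtype=bool)
    key_mask = np.asarray(key_mask, dtype=bool)
    weights = masked_softmax(logits, key_mask.reshape((1,) * (logits.ndim - key_mask.ndim) + key_mask.shape)
                             if key_mask.ndim < logits.ndim else key_mask)
    return weights.matmul(V), weights


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=shape or (fan_in, fan_out))


class Dense:
    def __init__(self, rng, d_in: int, d_out: int):
        self.W = Tensor(_glorot(rng, d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.W) + self.b

    def params(self):
        return [self.W, self.b]


class MultiHeadAttention:
    """Multi-head scaled-dot-product attention with the four-term relative
    positional decomposition (content-content, content-position,
    global-content, global-position)."""

    def __init__(self, rng, cfg: ModelConfig):
        d = cfg.d_model
        self.cfg = cfg
        self.Wq = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.Wk = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.Wv = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.Wo = Tensor(_glorot(rng, d, d), requires_grad=True)
        # relative-position parameters (zeroing all three removes every
        # position-dependent term from the logits)
        self.Wr = Tensor(_glorot(rng, d, d), requires_grad=True)
        self.u = Tensor(np.zeros((cfg.n_heads, cfg.d_k)), requires_grad=True)
        self.v = Tensor(np.zeros((cfg.n_heads, cfg.d_k)), requires_grad=True)

    def params(self):
        ps = [self.Wq, self.Wk, self.Wv, self.Wo]
        if self.cfg.relative_position:
            ps += [self.Wr, self.u, self.v]
        return ps

    def _split(self, x: Tensor, B: int, L: int) -> Tensor:
        h, dk = self.cfg.n_heads, self.cfg.d_k
        return x.reshape(B, L, h, dk).transpose(0, 2, 1, 3)  # (B, h, L, dk)

    def __call__(self, x: Tensor, key_mask: np.ndarray, return_weights: bool = False):
        B, L, d = x.shape
        h, dk = self.cfg.n_heads, self.cfg.d_k
        Q = self._split(x.matmul(self.Wq), B, L)
        K = self._split(x.matmul(self.Wk), B, L)
        V = self._split(x.matmul(self.Wv), B, L)
        scale = 1.0 / np.sqrt(dk)
        if self.cfg.relative_position:
            u = self.u.reshape(1, h, 1, dk)
            v = self.v.reshape(1, h, 1, dk)
            ac = (Q + u).matmul(K.transpose(0, 1, 3, 2))
            R = Tensor(sinusoidal_relative_encodings(L, d))
            RW = R.matmul(self.Wr).reshape(2 * L - 1, h, dk).transpose(1, 0, 2)  # (h, 2L-1, dk)
            bd_scores = (Q + v).matmul(RW.transpose(0, 2, 1))                    # (B, h, L, 2L-1)
            logits = (ac + rel_gather(bd_scores, L)) * scale
        else:
            logits = Q.matmul(K.transpose(0, 1, 3, 2)) * scale
        weights = masked_softmax(logits, key_mask[:, None, None, :])
        out = weights.matmul(V).transpose(0, 2, 1, 3).reshape(B, L, d).matmul(self.Wo)
        if return_weights:
            return out, weights
        return out

    def position_bias_matrix(self, L: int) -> np.ndarray:
        """Content-independent part of the logits: v · (R Wr) per head,
        gathered to (h, L, L). Toeplitz in j - i by construction."""
        h, dk = self.cfg.n_heads, self.cfg.d_k
        R = sinusoidal_relative_encodings(L, self.cfg.d_model)
        RW = (R @ self.Wr.data).reshape(2 * L - 1, h, dk).transpose(1, 0, 2)
        s = np.einsum("hd,hrd->hr", self.v.data, RW)        # (h, 2L-1)
        i = np.arange(L)[:, None]
        j = np.arange(L)[None, :]
        return s[:, i - j + (L - 1)] / np.sqrt(dk)


class TransformerLayer:
    """Post-norm block: LN(x + MHA(x)) then LN(· + FFN(·))."""

    def __init__(self, rng, cfg: ModelConfig):
        d = cfg.d_model
        self.cfg = cfg
        self.mha = MultiHeadAttention(rng, cfg)
        self.ff1 = Dense(rng, d, cfg.ffn_dim)
        self.ff2 = Dense(rng, cfg.ffn_dim, d)
        self.g1 = Tensor(np.ones(d), requires_grad=True)
        self.b1 = Tensor(np.zeros(d), requires_grad=True)
        self.g2 = Tensor(np.ones(d), requires_grad=True)
        self.b2 = Tensor(np.zeros(d), requires_grad=True)

    def params(self):
        return (self.mha.params() + self.ff1.params() + self.ff2.params()
                + [self.g1, self.b1, self.g2, self.b2])

    def __call__(self, x: Tensor, key_mask: np.ndarray, dropout_fn, return_weights=False):
        if return_weights:
            att, w = self.mha(x, key_mask, return_weights=True)
        else:
            att = self.mha(x, key_mask)
            w = None
        y = layer_norm(x + dropout_fn(att), self.g1, self.b1)
        ff = self.ff2(dropout_fn(self.ff1(y).relu()))
        z = layer_norm(y + dropout_fn(ff), self.g2, self.b2)
        return (z, w) if return_weights else z


class SpatialModel:
    """Full network: encoders -> transformer stack -> Tanh head
    (+ optional adversarial domain classifier)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        self.seq_enc = [Dense(rng, c.seq_dim, c.encoder_hidden),
                        Dense(rng, c.encoder_hidden, c.encoder_out)]
        self.epi_enc = [Dense(rng, c.epi_dim, c.encoder_hidden),
                        Dense(rng, c.encoder_hidden, c.encoder_out)]
        self.layers = [TransformerLayer(rng, c) for _ in range(c.n_layers)]
        self.head = Dense(rng, c.d_model, 1)
        if c.domain_head:
            if c.domain_hidden > 0:
                self.domain_clf = [Dense(rng, c.d_model, c.domain_hidden),
                                   Dense(rng, c.domain_hidden, c.n_domains)]
            else:
                self.domain_clf = [Dense(rng, c.d_model, c.n_domains)]
        else:
            self.domain_clf = None
        self._drop_rng = np.random.default_rng(seed + 1)
        self.training = False

    # ---------------------------------------------------------------- params
    def params(self):
        ps = []
        for layer in self.seq_enc + self.epi_enc:
            ps += layer.params()
        for tl in self.layers:
            ps += tl.params()
        ps += self.head.params()
        if self.domain_clf is not None:
            for layer in self.domain_clf:
                ps += layer.params()
        return ps

    def transformer_params(self):
        """Everything upstream of the gradient-reversal layer."""
        ps = []
        for layer in self.seq_enc + self.epi_enc:
            ps += layer.params()
        for tl in self.layers:
            ps += tl.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params())

    def zero_grad(self):
        for p in self.params():
            p.zero_grad()

    def train(self):
        self.training = True
        return self

    def eval(self):
        self.training = False
        return self

    def _dropout(self, x: Tensor) -> Tensor:
        p = self.config.dropout
        if not self.training or p <= 0:
            return x
        keep = self._drop_rng.random(x.shape) >= p
        return x * Tensor(keep / (1.0 - p))

    # --------------------------------------------------------------- forward
    def encode(self, seq_x: Tensor, epi_x: Tensor) -> Tensor:
        s, e = seq_x, epi_x
        for layer in self.seq_enc:
            s = layer(s).relu()
        for layer in self.epi_enc:
            e = layer(e).relu()
        return concat([s, e], axis=-1)

    def forward_tensors(self, seq_x: Tensor, epi_x: Tensor, key_mask: np.ndarray,
                        grl_lambda: float = 0.0, return_attention: bool = False):
        """Forward pass on Tensors (differentiable end to end).

        seq_x: (B, L, seq_dim); epi_x: (B, L, epi_dim); key_mask: (B, L) bool.
        Returns (predictions, domain_logits or None, attention list or None);
        predictions are (B,) in center mode, (B, L) otherwise.
        """
        key_mask = np.asarray(key_mask, dtype=bool)
        if not key_mask.any(axis=-1).all():
            raise ValueError("window with all positions padded")
        x = self.encode(seq_x, epi_x)
        attn = [] if return_attention else None
        for tl in self.layers:
            if return_attention:
                x, w = tl(x, key_mask, self._dropout, return_weights=True)
                attn.append(w.data)
            else:
                x = tl(x, key_mask, self._dropout)
        raw = self.head(x).tanh()                    # (B, L, 1)
        B, L, _ = raw.shape
        if self.config.prediction_mode == "center":
            preds = raw[:, self.config.window, 0]
        else:
            preds = raw.reshape(B, L)
        dom = None
        if self.domain_clf is not None:
            mw = key_mask.astype(np.float64)
            mw = mw / mw.sum(axis=1, keepdims=True)
            pooled = (x * Tensor(mw[:, :, None])).sum(axis=1)   # masked mean pool
            dom = grad_reverse(pooled, grl_lambda)
            for layer in self.domain_clf[:-1]:
                dom = layer(dom).relu()
            dom = self.domain_clf[-1](dom)
        return preds, dom, attn

    def predict(self, seq_x: np.ndarray, epi_x: np.ndarray, key_mask: np.ndarray):
        """Evaluation-mode numpy predictions."""
        was = self.training
        self.eval()
        preds, _, _ = self.forward_tensors(Tensor(seq_x), Tensor(epi_x), key_mask)
        self.training = was
        return preds.data

    # ------------------------------------------------------------ checkpoint
    def save(self, path) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params())}
        arrays["config_json"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, expect_seq_dim: int | None = None,
             expect_epi_dim: int | None = None) -> "SpatialModel":
        with np.load(path) as z:
            cfg = ModelConfig(**json.loads(bytes(z["config_json"].tobytes()).decode()))
            if expect_seq_dim is not None and cfg.seq_dim != expect_seq_dim:
                raise ValueError("checkpoint sequence-feature dimension mismatch")
            if expect_epi_dim is not None and cfg.epi_dim != expect_epi_dim:
                raise ValueError("checkpoint epigenomic-feature dimension mismatch")
            model = cls(cfg, seed=0)
            for i, p in enumerate(model.params()):
                arr = z[f"p{i}"]
                if arr.shape != p.data.shape:
                    raise ValueError("checkpoint parameter shape mismatch")
                p.data = arr.copy()
        return model


def parameter_count(cfg: ModelConfig) -> int:
    """Closed-form parameter count implied by a config."""
    d, h, f = cfg.d_model, cfg.encoder_hidden, cfg.ffn_dim
    enc = (cfg.seq_dim * h + h) + (h * cfg.encoder_out + cfg.encoder_out)
    enc += (cfg.epi_dim * h + h) + (h * cfg.encoder_out + cfg.encoder_out)
    per_layer = 4 * (d * d)                      # Wq, Wk, Wv, Wo
    if cfg.relative_position:
        per_layer += d * d + 2 * cfg.n_heads * cfg.d_k   # Wr, u, v
    per_layer += (d * f + f) + (f * d + d)       # FFN
    per_layer += 4 * d                           # two LayerNorms
    head = d * 1 + 1
    dom = 0
    if cfg.domain_head:
        if cfg.domain_hidden > 0:
            dom = (d * cfg.domain_hidden + cfg.domain_hidden
                   + cfg.domain_hidden * cfg.n_domains + cfg.n_domains)
        else:
            dom = d * cfg.n_domains + cfg.n_domains
    return enc + cfg.n_layers * per_layer + head + dom
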