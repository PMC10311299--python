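"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine supports exactly the operations the network needs: broadcasted
arithmetic, (batched) matrix products, ReLU/Tanh, masked softmax, layer
normalization, slicing/concatenation, a relative-position gather, and a
gradient-reversal node. Gradients are accumulated into ``.grad`` by
``backward()`` over a topologically sorted graph.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "concat",
    "masked_softmax",
    "layer_norm",
    "log_softmax",
    "grad_reverse",
    "rel_gather",
    "shift1d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # remove leading broadcast axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an attached gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: "Tensor") -> None:
            stack = [(t, iter(t._parents))]
            seen.add(id(t))
            while stack:
                node, it = stack[-1]
                advanced = False
                for p in it:
                    if id(p) not in seen and p.requires_grad:
                        seen.add(id(p))
                        stack.append((p, iter(p._parents)))
                        advanced = True
                        break
                if not advanced:
                    topo.append(node)
                    stack.pop()

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def item(self) -> float:
        return float(self.data)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            raise TypeError("division by Tensor not supported; multiply by reciprocal")
        return self * (1.0 / float(other))

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1))

        out._backward = bw
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = _as_tensor(other)
        out = Tensor(np.matmul(self.data, other.data), parents=(self, other))

        def bw(g):
            if self.requires_grad:
                ga = np.matmul(g, np.swapaxes(other.data, -1, -2))
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.matmul(np.swapaxes(self.data, -1, -2), g)
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # ------------------------------------------------------------ activations
    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        y = np.tanh(self.data)
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bw
        return out

    def exp(self) -> "Tensor":
        y = np.exp(self.data)
        out = Tensor(y, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = bw
        return out

    # -------------------------------------------------------------- reshaping
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes) -> "Tensor":
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out = Tensor(self.data.transpose(axes), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    # ------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def tensor(data, requires_grad: bool = False) -> Tensor:
    return Tensor(data, requires_grad=requires_grad)


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = bw
    return out


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to ``mask`` (True = keep).

    Masked entries receive probability exactly 0. Raises if any row has no
    valid entry.
    """
    mask = np.broadcast_to(np.asarray(mask, dtype=bool), logits.data.shape)
    if not mask.any(axis=-1).all():
        raise ValueError("masked_softmax: some rows have no unmasked entries")
    z = np.where(mask, logits.data, -np.inf)
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=-1, keepdims=True)
    out = Tensor(p, parents=(logits,))

    def bw(g):
        if logits.requires_grad:
            dot = (g * p).sum(axis=-1, keepdims=True)
            logits._accum(p * (g - dot))

    out._backward = bw
    return out


def log_softmax(logits: Tensor) -> Tensor:
    z = logits.data - logits.data.max(axis=-1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    y = z - lse
    out = Tensor(y, parents=(logits,))
    p = np.exp(y)

    def bw(g):
        if logits.requires_grad:
            logits._accum(g - p * g.sum(axis=-1, keepdims=True))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalization over the last axis: gamma * (x-mu)/sigma + beta."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, parents=(x, gamma, beta))
    n = x.data.shape[-1]

    def bw(g):
        if gamma.requires_grad:
            gamma._accum(_unbroadcast(g * xhat, gamma.data.shape))
        if beta.requires_grad:
            beta._accum(_unbroadcast(g, beta.data.shape))
        if x.requires_grad:
            gx = g * gamma.data
            term = gx - gx.mean(axis=-1, keepdims=True) - xhat * (gx * xhat).mean(axis=-1, keepdims=True)
            x._accum(term * inv)

    out._backward = bw
    return out


def grad_reverse(x: Tensor, lam: float) -> Tensor:
    """Identity in the forward pass; multiplies the gradient by -lam."""
    if lam < 0:
        raise ValueError("gradient-reversal coefficient must be non-negative")
    out = Tensor(x.data.copy(), parents=(x,))

    def bw(g):
        if x.requires_grad:
            x._accum(-lam * g)

    out._backward = bw
    return out


def rel_gather(scores: Tensor, L: int) -> Tensor:
    """Gather relative-offset scores into pairwise form.

    ``scores`` has shape (..., L, 2L-1) where column r holds the score for
    relative offset ``i - j = r - (L-1)``. Returns (..., L, L) with
    ``out[..., i, j] = scores[..., i, i - j + L - 1]``.
    """
    if scores.data.shape[-2] != L or scores.data.shape[-1] != 2 * L - 1:
        raise ValueError("rel_gather: expected shape (..., L, 2L-1)")
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    idx = i - j + (L - 1)
    out = Tensor(scores.data[..., i, idx], parents=(scores,))

    def bw(g):
        if scores.requires_grad:
            full = np.zeros_like(scores.data)
            np.add.at(full, (..., np.arange(L)[:, None], idx), g)
            scores._accum(full)

    out._backward = bw
    return out


def shift1d(x: Tensor, offset: int) -> Tensor:
    """Shift along axis -2 (positions) by ``offset`` with zero padding.

    ``out[..., i, :] = x[..., i + offset, :]`` where out-of-range reads are 0.
    Used to express 1-D convolutions as sums of shifted dense maps.
    """
    L = x.data.shape[-2]
    y = np.zeros_like(x.data)
    if offset >= 0:
        n = L - offset
        if n > 0:
            y[..., :n, :] = x.data[..., offset:, :]
    else:
        n = L + offset
        if n > 0:
            y[..., -n:, :] = x.data[..., :n, :]
    out = Tensor(y, parents=(x,))

    def bw(g):
        if not x.requires_grad:
            return
        gx = np.zeros_like(x.data)
        if offset >= 0:
            n = L - offset
            if n > 0:
                gx[..., offset:, :] = g[..., :n, :]
        else:
            n = L + offset
            if n > 0:
                gx[..., :n, :] = g[..., -n:, :]
        x._accum(gx)

    out._backward = bw
    return out
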