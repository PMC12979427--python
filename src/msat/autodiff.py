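"""Minimal vectorised reverse-mode automatic differentiation over numpy.

The encoder and scorer in this package need gradients for a fairly small set
of array operations (dense matmuls, elementwise nonlinearities, gather /
scatter-add over edge index arrays, reductions). This module provides exactly
those primitives on float64 numpy arrays, plus an AdamW optimizer and global
gradient-norm clipping. Graphs are built eagerly per forward pass and freed
after ``backward``.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "parameter",
    "add", "sub", "mul", "div", "neg", "matmul", "pow_",
    "relu", "sigmoid", "exp", "log", "sqrt",
    "sum_", "mean_", "reshape", "concat",
    "rows", "segment_sum", "segment_softmax",
    "dropout", "layer_norm", "bce_with_logits",
    "AdamW", "clip_grad_norm", "xavier_uniform",
]


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape})"

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    def __radd__(self, other):
        return add(_wrap(other), self)

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __rsub__(self, other):
        return sub(_wrap(other), self)

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __truediv__(self, other):
        return div(self, _wrap(other))

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def backward(self):
        """Backpropagate from this (scalar or array) tensor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))


def constant(x) -> Tensor:
    return _wrap(x)


def parameter(x) -> Tensor:
    return Tensor(np.array(x, dtype=np.float64, copy=True))


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


# -- elementwise arithmetic ---------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data
    def back(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)
    return Tensor(out_data, (a, b), back)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data
    def back(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(-g, b.data.shape)
    return Tensor(out_data, (a, b), back)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data
    def back(g):
        return (_unbroadcast(g * b.data, a.data.shape),
                _unbroadcast(g * a.data, b.data.shape))
    return Tensor(out_data, (a, b), back)


def div(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data / b.data
    def back(g):
        return (_unbroadcast(g / b.data, a.data.shape),
                _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))
    return Tensor(out_data, (a, b), back)


def neg(a: Tensor) -> Tensor:
    return Tensor(-a.data, (a,), lambda g: (-g,))


def pow_(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p
    def back(g):
        return (g * p * a.data ** (p - 1),)
    return Tensor(out_data, (a,), back)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)
    def back(g):
        return (g * 0.5 / out_data,)
    return Tensor(out_data, (a,), back)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data
    def back(g):
        return g @ b.data.T, a.data.T @ g
    return Tensor(out_data, (a, b), back)


# -- nonlinearities -------------------------------------------------------

def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    return Tensor(a.data * mask, (a,), lambda g: (g * mask,))


def sigmoid(a: Tensor) -> Tensor:
    out_data = _sigmoid(a.data)
    def back(g):
        return (g * out_data * (1.0 - out_data),)
    return Tensor(out_data, (a,), back)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)
    return Tensor(out_data, (a,), lambda g: (g * out_data,))


def log(a: Tensor) -> Tensor:
    return Tensor(np.log(a.data), (a,), lambda g: (g / a.data,))


# -- reductions / reshaping ----------------------------------------------

def sum_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    def back(g):
        if axis is None:
            return (np.broadcast_to(g, a.data.shape).copy(),)
        g2 = g if keepdims else np.expand_dims(g, axis)
        return (np.broadcast_to(g2, a.data.shape).copy(),)
    return Tensor(out_data, (a,), back)


def mean_(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape) -> Tensor:
    orig = a.data.shape
    return Tensor(a.data.reshape(shape), (a,), lambda g: (g.reshape(orig),))


def concat(tensors, axis=0) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]
    def back(g):
        return tuple(np.split(g, splits, axis=axis))
    return Tensor(out_data, tuple(tensors), back)


# -- indexed ops over edge arrays -----------------------------------------

def rows(a: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows ``a[idx]``; gradient scatter-adds back."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = a.data[idx]
    def back(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        return (ga,)
    return Tensor(out_data, (a,), back)


def segment_sum(a: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """out[s] = sum of a[e] over rows e with idx[e] == s."""
    idx = np.asarray(idx, dtype=np.intp)
    out_data = np.zeros((num_segments,) + a.data.shape[1:], dtype=np.float64)
    np.add.at(out_data, idx, a.data)
    def back(g):
        return (g[idx],)
    return Tensor(out_data, (a,), back)


def segment_softmax(logits: Tensor, idx: np.ndarray, num_segments: int) -> Tensor:
    """Softmax of per-edge logits within groups sharing a destination index.

    Numerically stabilised by a per-segment max (treated as a constant).
    """
    idx = np.asarray(idx, dtype=np.intp)
    seg_max = np.full((num_segments,) + logits.data.shape[1:], -np.inf)
    np.maximum.at(seg_max, idx, logits.data)
    seg_max[~np.isfinite(seg_max)] = 0.0  # empty segments
    z = exp(sub(logits, Tensor(seg_max[idx])))
    denom = segment_sum(z, idx, num_segments)
    return div(z, rows(denom, idx))


# -- structured layers -----------------------------------------------------

def dropout(a: Tensor, rate: float, rng: np.random.Generator | None,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return a
    if rng is None:
        raise ValueError("dropout in training mode requires an rng")
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


def layer_norm(a: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = mean_(a, axis=-1, keepdims=True)
    xc = sub(a, mu)
    var = mean_(mul(xc, xc), axis=-1, keepdims=True)
    xhat = div(xc, sqrt(add(var, Tensor(eps))))
    return add(mul(xhat, gamma), beta)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on raw logits (numerically stable)."""
    y = np.asarray(targets, dtype=np.float64)
    s = logits.data
    loss = np.maximum(s, 0) - s * y + np.log1p(np.exp(-np.abs(s)))
    n = s.size
    def back(g):
        return ((_sigmoid(s) - y) * (g / n),)
    return Tensor(loss.mean(), (logits,), back)


# -- optimisation -----------------------------------------------------------

class AdamW:
    """AdamW with decoupled weight decay over a name->Tensor parameter dict."""

    def __init__(self, params: dict[str, Tensor], lr: float,
                 weight_decay: float = 0.0, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            m = self._m[k]
            v = self._v[k]
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / bc1
            vhat = v / bc2
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps)
                                 + self.weight_decay * p.data)


def clip_grad_norm(params: dict[str, Tensor], max_norm: float) -> float:
    """Scale all gradients so the global L2 norm is at most ``max_norm``.

    Returns the pre-clip global norm.
    """
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float(np.sum(p.grad ** 2))
    norm = math.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = max_norm / norm
        for p in params.values():
            if p.grad is not None:
                p.grad *= scale
    return norm


def xavier_uniform(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[1]
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)
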