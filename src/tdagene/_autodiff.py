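"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine carrying exactly the operations the
model needs: dense linear algebra, the usual pointwise nonlinearities, row
gathering for edge batches, a masked row-softmax for graph attention, and
layer normalization.  Everything is float64; graphs here are a few hundred
nodes, so clarity and exact gradient checks win over throughput.

Gradients are validated against central finite differences in the test
suite; any new primitive added here must come with such a check.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "Tensor",
    "parameter",
    "concat",
    "gather_rows",
    "leaky_relu",
    "elu",
    "sigmoid",
    "log",
    "clip",
    "masked_softmax",
    "layer_norm",
    "dropout",
    "glorot_uniform",
    "Adam",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping.

    ``requires_grad`` is inherited from parents, so intermediate nodes only
    keep a tape entry when some ancestor is a trainable parameter.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents: tuple = ()):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad or any(p.requires_grad for p in _parents)
        self.grad: np.ndarray | None = None
        self._parents = _parents if self.requires_grad else ()
        self._backward = None

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate d(self)/d(leaf) for every reachable parameter."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accum(np.ones_like(self.data))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()

    # -- arithmetic -------------------------------------------------------

    def __add__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data + other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(-out.grad)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data * other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = _as_tensor(other)
        out = Tensor(self.data @ other.data, _parents=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(out.grad @ other.data.T)
            if other.requires_grad:
                other._accum(self.data.T @ out.grad)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _parents=(self,))

        def bw():
            if self.requires_grad:
                g = out.grad
                if axis is not None and not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def transpose(self):
        out = Tensor(self.data.T, _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.T)

        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _parents=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))

        out._backward = bw
        return out


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


# -- functional ops -------------------------------------------------------


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw():
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * out.grad.ndim
                idx[axis] = slice(lo, hi)
                t._accum(out.grad[tuple(idx)])

    out._backward = bw
    return out


def gather_rows(x: Tensor, idx) -> Tensor:
    """Select rows ``x[idx]``; duplicate indices accumulate gradient."""
    idx = np.asarray(idx, dtype=np.intp)
    out = Tensor(x.data[idx], _parents=(x,))

    def bw():
        if x.requires_grad:
            g = np.zeros_like(x.data)
            np.add.at(g, idx, out.grad)
            x._accum(g)

    out._backward = bw
    return out


def leaky_relu(x: Tensor, slope: float) -> Tensor:
    neg = x.data < 0
    out = Tensor(np.where(neg, slope * x.data, x.data), _parents=(x,))

    def bw():
        if x.requires_grad:
            x._accum(np.where(neg, slope, 1.0) * out.grad)

    out._backward = bw
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    neg = x.data < 0
    ex = alpha * (np.exp(np.minimum(x.data, 0.0)) - 1.0)
    out = Tensor(np.where(neg, ex, x.data), _parents=(x,))

    def bw():
        if x.requires_grad:
            x._accum(np.where(neg, ex + alpha, 1.0) * out.grad)

    out._backward = bw
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = np.where(x.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(x.data))),
                 np.exp(-np.abs(x.data)) / (1.0 + np.exp(-np.abs(x.data))))
    out = Tensor(s, _parents=(x,))

    def bw():
        if x.requires_grad:
            x._accum(s * (1.0 - s) * out.grad)

    out._backward = bw
    return out


def log(x: Tensor) -> Tensor:
    out = Tensor(np.log(x.data), _parents=(x,))

    def bw():
        if x.requires_grad:
            x._accum(out.grad / x.data)

    out._backward = bw
    return out


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp with pass-through gradient inside the interval, zero outside."""
    inside = (x.data >= lo) & (x.data <= hi)
    out = Tensor(np.clip(x.data, lo, hi), _parents=(x,))

    def bw():
        if x.requires_grad:
            x._accum(np.where(inside, out.grad, 0.0))

    out._backward = bw
    return out


def masked_softmax(e: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise softmax restricted to ``mask`` (boolean, same shape).

    Rows must contain at least one allowed entry (guaranteed upstream by
    self-loops).  Max-subtraction keeps the exponentials safe.
    """
    x = np.where(mask, e.data, -np.inf)
    x = x - x.max(axis=1, keepdims=True)
    ex = np.exp(x)
    ex[~mask] = 0.0
    a = ex / ex.sum(axis=1, keepdims=True)
    out = Tensor(a, _parents=(e,))

    def bw():
        if e.requires_grad:
            g = out.grad
            dot = (g * a).sum(axis=1, keepdims=True)
            e._accum(a * (g - dot))

    out._backward = bw
    return out


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-row layer normalization with learnable affine parameters."""
    mu = x.data.mean(axis=-1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = Tensor(gamma.data * xhat + beta.data, _parents=(x, gamma, beta))
    d = x.data.shape[-1]

    def bw():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=tuple(range(g.ndim - 1))))
        if beta.requires_grad:
            beta._accum(g.sum(axis=tuple(range(g.ndim - 1))))
        if x.requires_grad:
            dxhat = g * gamma.data
            term1 = dxhat
            term2 = dxhat.mean(axis=-1, keepdims=True)
            term3 = xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (term1 - term2 - term3))

    out._backward = bw
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator, training: bool) -> Tensor:
    """Inverted dropout; identity when not training or rate == 0."""
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return parameter(rng.uniform(-limit, limit, size=shape))


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
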