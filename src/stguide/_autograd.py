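"""Minimal reverse-mode automatic differentiation on numpy arrays.

The graph attention autoencoder at the core of this package is small
(two layers, desk-scale graphs), so instead of depending on a deep
learning framework we differentiate through a tiny tape: a :class:`Tensor`
wraps an ``ndarray`` and records the closure needed to push gradients to
its parents.  Only the primitives the model needs are provided.  All
gradients are checked against central finite differences in the test
suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "constant", "parameter", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` to undo numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    # -- infrastructure ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Accumulate gradients of ``self`` (a scalar unless seeded)."""
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() on non-scalar requires a seed")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(seed, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = grad.copy()
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g, a.shape))
            b._accum(_unbroadcast(g, b.shape))

        return Tensor(self.data + other.data, parents=(self, other), backward=bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            a._accum(-g)

        return Tensor(-self.data, parents=(self,), backward=bwd)

    def __sub__(self, other):
        return self + (-_as_tensor(other))

    def __rsub__(self, other):
        return _as_tensor(other) + (-self)

    def __mul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accum(_unbroadcast(g * b.data, a.shape))
            b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor(self.data * other.data, parents=(self, other), backward=bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * _as_tensor(other) ** -1.0

    def __rtruediv__(self, other):
        return _as_tensor(other) * self**-1.0

    def __pow__(self, exponent: float):
        e = float(exponent)

        def bwd(g, a=self):
            a._accum(g * e * a.data ** (e - 1.0))

        return Tensor(self.data**e, parents=(self,), backward=bwd)

    def __matmul__(self, other):
        other = _as_tensor(other)

        def bwd(g, a=self, b=other):
            a._accum(g @ b.data.T)
            b._accum(a.data.T @ g)

        return Tensor(self.data @ other.data, parents=(self, other), backward=bwd)

    @property
    def T(self):
        def bwd(g, a=self):
            a._accum(g.T)

        return Tensor(self.data.T, parents=(self,), backward=bwd)

    # -- reductions ----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def bwd(g, a=self):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor(
            self.data.sum(axis=axis, keepdims=keepdims), parents=(self,), backward=bwd
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)

        def bwd(g, a=self, o=out_data):
            a._accum(g * o)

        return Tensor(out_data, parents=(self,), backward=bwd)

    def log(self):
        def bwd(g, a=self):
            a._accum(g / a.data)

        return Tensor(np.log(self.data), parents=(self,), backward=bwd)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def bwd(g, a=self, o=out_data):
            a._accum(g * o * (1.0 - o))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(self.data))

        def bwd(g, a=self, o=out_data, p=pos):
            a._accum(g * np.where(p, 1.0, o + alpha))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def leaky_relu(self, negative_slope: float = 0.2):
        pos = self.data > 0

        def bwd(g, a=self, p=pos):
            a._accum(g * np.where(p, 1.0, negative_slope))

        return Tensor(
            np.where(pos, self.data, negative_slope * self.data),
            parents=(self,),
            backward=bwd,
        )

    def softmax_rows(self):
        """Numerically stable softmax along the last axis."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def bwd(g, a=self, o=out_data):
            dot = (g * o).sum(axis=-1, keepdims=True)
            a._accum(o * (g - dot))

        return Tensor(out_data, parents=(self,), backward=bwd)

    def clip(self, lo: float, hi: float):
        inside = (self.data > lo) & (self.data < hi)

        def bwd(g, a=self, m=inside):
            a._accum(g * m)

        return Tensor(np.clip(self.data, lo, hi), parents=(self,), backward=bwd)

    # -- structural ----------------------------------------------------
    def take_rows(self, idx: np.ndarray):
        idx = np.asarray(idx, dtype=np.intp)

        def bwd(g, a=self, i=idx):
            full = np.zeros_like(a.data)
            np.add.at(full, i, g)
            a._accum(full)

        return Tensor(self.data[idx], parents=(self,), backward=bwd)

    def detach(self):
        return Tensor(self.data.copy())

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    return Tensor(x)


def parameter(x) -> Tensor:
    return Tensor(x, requires_grad=True)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None):
    """Glorot/Xavier uniform initialization."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    if shape is None:
        shape = (fan_in, fan_out)
    return rng.uniform(-limit, limit, size=shape)


class Adam:
    """Adam with decoupled-from-nothing, torch-style L2 weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]
        self._t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self._t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1**self._t)
            vhat = self._v[i] / (1 - self.b2**self._t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
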