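"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tensor engine — dynamic graph, scalar-or-array nodes, broadcasting —
sufficient to train the recurrent and convolutional blocks in this package
on a single CPU.  Gradients are validated against central finite differences
in the test suite.  Not a general deep-learning framework: only the ops the
package needs exist, and everything is float64 for reproducibility.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "gather_rows", "dropout",
           "softmax_cross_entropy", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the autodiff graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = tuple(_prev)

    # -- infrastructure ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        order, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            order.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(order):
            if t._backward is not None and t.requires_grad:
                t._backward()

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw():
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __pow__(self, k: float):
        out = Tensor(self.data ** k, _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * k * self.data ** (k - 1))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw():
            g = out.grad
            if self.requires_grad:
                if other.data.ndim == 1:
                    gs = (np.outer(g, other.data) if self.data.ndim == 2
                          else g * other.data)
                else:
                    gs = g @ other.data.swapaxes(-1, -2)
                self._accum(_unbroadcast(gs, self.shape))
            if other.requires_grad:
                if self.data.ndim == 1:
                    go = (np.outer(self.data, g) if other.data.ndim == 2
                          else self.data * g)
                else:
                    go = self.data.swapaxes(-1, -2) @ g
                other._accum(_unbroadcast(go, other.shape))
        out._backward = bw
        return out

    # -- nonlinearities ----------------------------------------------------
    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (1.0 - out.data ** 2))
        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * out.data * (1.0 - out.data))
        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))
        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad * out.data)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad / self.data)
        out._backward = bw
        return out

    # -- shape / reduction -------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

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

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw():
            if self.requires_grad:
                self._accum(out.grad.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(self.data.transpose(axes), _prev=(self,))

        def bw():
            if self.requires_grad:
                inv = np.argsort(axes) if axes else None
                self._accum(out.grad.transpose(inv))
        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw():
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)
        out._backward = bw
        return out

    def pad_left(self, n: int, axis: int = -1):
        """Zero-pad ``n`` entries on the left of ``axis`` (causal padding)."""
        widths = [(0, 0)] * self.data.ndim
        widths[axis] = (n, 0)
        out = Tensor(np.pad(self.data, widths), _prev=(self,))

        def bw():
            if self.requires_grad:
                sl = [slice(None)] * self.data.ndim
                sl[axis] = slice(n, None)
                self._accum(out.grad[tuple(sl)])
        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))

    def bw():
        start = 0
        for t in tensors:
            size = t.data.shape[axis]
            sl = [slice(None)] * out.data.ndim
            sl[axis] = slice(start, start + size)
            if t.requires_grad:
                t._accum(out.grad[tuple(sl)])
            start += size
    out._backward = bw
    return out


def gather_rows(t: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``t[i, idx[i]]`` for each row i (for cross-entropy)."""
    rows = np.arange(len(idx))
    out = Tensor(t.data[rows, idx], _prev=(t,))

    def bw():
        if t.requires_grad:
            g = np.zeros_like(t.data)
            g[rows, idx] = out.grad
            t._accum(g)
    out._backward = bw
    return out


def dropout(t: Tensor, p: float, rng: np.random.Generator,
            train: bool = True) -> Tensor:
    """Inverted dropout; identity when ``train`` is False or p == 0."""
    if not train or p <= 0:
        return t
    mask = (rng.random(t.shape) >= p) / (1.0 - p)
    return t * Tensor(mask)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    m = Tensor(logits.data.max(axis=1, keepdims=True))  # constant shift
    z = logits - m
    lse = z.exp().sum(axis=1, keepdims=True).log()
    logp = z - lse
    return -gather_rows(logp, labels).mean()


class Adam:
    """Adam optimizer (beta1 = the gradient decay factor)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
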