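"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small engine: just the operations the methylation networks
need (dense algebra, 1-D convolution/pooling, gated recurrences, batch
normalisation).  Everything is float64 and purely deterministic, which keeps
training reproducible bit-for-bit for a fixed seed and makes finite-
difference gradient checks meaningful.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` over broadcast dimensions so it matches `shape`."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = tuple(_prev)

    # ---- infrastructure -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, seed: np.ndarray | None = None) -> None:
        """Backpropagate; `seed` defaults to ones (scalar outputs)."""
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
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.ones_like(self.data) if seed is None
                         else np.asarray(seed, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- elementwise arithmetic ----------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _backward(g):
            self._accumulate(_unbroadcast(g, self.data.shape))
            other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = _backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _backward(g):
            self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _backward
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * Tensor(-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return self._lift(other) * self ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def _backward(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = _backward
        return out

    # ---- nonlinearities -------------------------------------------------

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g * out.data)

        out._backward = _backward
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g / self.data)

        out._backward = _backward
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = _backward
        return out

    def sigmoid(self):
        out = Tensor(expit(self.data), _prev=(self,))

        def _backward(g):
            self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = _backward
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))

        def _backward(g):
            self._accumulate(g * (self.data > 0.0))

        out._backward = _backward
        return out

    # ---- linear algebra & shape ----------------------------------------

    def __matmul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _backward(g):
            self._accumulate(g @ other.data.T)
            other._accumulate(self.data.T @ g)

        out._backward = _backward
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def _backward(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = _backward
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))

        def _backward(g):
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).copy()
                                 if np.ndim(g) else np.full_like(self.data, g))
                return
            gg = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % self.data.ndim for a in axes):
                    gg = np.expand_dims(gg, ax)
            self._accumulate(np.broadcast_to(gg, self.data.shape).copy())

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def _backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accumulate(full)

        out._backward = _backward
        return out


def concat(tensors, axis: int = -1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def _backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = _backward
    return out


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Valid-mode 1-D convolution via im2col.

    x: (batch, length, channels); w: (k * channels, filters); b: (filters,).
    Returns (batch, length - k + 1, filters).
    """
    B, L, C = x.data.shape
    KC, F = w.data.shape
    k = KC // C
    if L < k:
        raise ValueError(f"input length {L} shorter than filter length {k}")
    idx = np.arange(L - k + 1)[:, None] + np.arange(k)[None, :]  # (L', k)
    cols = x.data[:, idx, :].reshape(B, L - k + 1, KC)
    out = Tensor(cols @ w.data + b.data, _prev=(x, w, b))

    def _backward(g):
        dcols = g @ w.data.T                       # (B, L', KC)
        dx = np.zeros_like(x.data)
        np.add.at(dx, (slice(None), idx), dcols.reshape(B, L - k + 1, k, C))
        x._accumulate(dx)
        w._accumulate(cols.reshape(-1, KC).T @ g.reshape(-1, F))
        b._accumulate(g.sum(axis=(0, 1)))

    out._backward = _backward
    return out


def maxpool1d(x: Tensor, k: int) -> Tensor:
    """Non-overlapping max pooling along axis 1; trailing remainder dropped."""
    B, L, C = x.data.shape
    Lp = L // k
    xr = x.data[:, :Lp * k, :].reshape(B, Lp, k, C)
    am = xr.argmax(axis=2)
    out = Tensor(np.take_along_axis(xr, am[:, :, None, :], axis=2)[:, :, 0, :],
                 _prev=(x,))

    def _backward(g):
        dxr = np.zeros_like(xr)
        np.put_along_axis(dxr, am[:, :, None, :], g[:, :, None, :], axis=2)
        dx = np.zeros_like(x.data)
        dx[:, :Lp * k, :] = dxr.reshape(B, Lp * k, C)
        x._accumulate(dx)

    out._backward = _backward
    return out
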