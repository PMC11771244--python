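"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package's models are full-batch and desk-scale (a few thousand spots,
a few thousand genes), so a small tape-based engine over dense/sparse NumPy
primitives is sufficient: every operation records its parents and a backward
closure, and :meth:`Tensor.backward` runs the tape in reverse topological
order.  Only the primitives the encoder, decoder and losses need are
implemented (broadcast arithmetic, matmul, exp/log, logistic, ELU,
reductions, row gather and segment sum).
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.special import expit

__all__ = ["Tensor", "as_tensor", "gather", "segment_sum", "diagonal", "concat_rows"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast so it matches `shape`."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the differentiation tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ---- construction helpers -------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # ---- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(self.data + other.data, (self, other), bw)

    __radd__ = __add__

    def __neg__(self):
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(self.data * other.data, (self, other), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(self.data / other.data, (self, other), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        def bw(g):
            if self.requires_grad:
                self._accumulate(g * p * self.data ** (p - 1))

        return Tensor._make(self.data**p, (self,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self.data, other.data

        def bw(g):
            # promote 1-D operands to 2-D so the adjoint rules apply uniformly
            a2 = a[None, :] if a.ndim == 1 else a
            b2 = b[:, None] if b.ndim == 1 else b
            g2 = g
            if a.ndim == 1:
                g2 = g2[None, ...]
            if b.ndim == 1:
                g2 = g2[..., None]
            if self.requires_grad:
                ga = g2 @ b2.T
                self._accumulate(ga[0] if a.ndim == 1 else ga)
            if other.requires_grad:
                gb = a2.T @ g2
                other._accumulate(gb[:, 0] if b.ndim == 1 else gb)

        return Tensor._make(a @ b, (self, other), bw)

    @property
    def T(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), bw)

    # ---- elementwise nonlinearities -------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor._make(out_data, (self,), bw)

    def log(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor._make(np.log(self.data), (self,), bw)

    def sqrt(self) -> "Tensor":
        out_data = np.sqrt(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / out_data)

        return Tensor._make(out_data, (self,), bw)

    def sigmoid(self) -> "Tensor":
        out_data = expit(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return Tensor._make(out_data, (self,), bw)

    def elu(self) -> "Tensor":
        pos = self.data > 0
        expm = np.expm1(np.minimum(self.data, 0.0))
        out_data = np.where(pos, self.data, expm)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.where(pos, 1.0, expm + 1.0))

        return Tensor._make(out_data, (self,), bw)

    # ---- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) / n

    # ---- autodiff driver -------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def gather(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows (axis 0) of `t`; backward scatter-adds."""
    idx = np.asarray(idx)

    def bw(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.add.at(acc, idx, g)
            t._accumulate(acc)

    return Tensor._make(t.data[idx], (t,), bw)


def segment_sum(t: Tensor, seg: np.ndarray, n_segments: int) -> Tensor:
    """Sum rows of `t` into `n_segments` buckets given per-row segment ids."""
    seg = np.asarray(seg)
    out_shape = (n_segments,) + t.data.shape[1:]
    out_data = np.zeros(out_shape, dtype=np.float64)
    np.add.at(out_data, seg, t.data)

    def bw(g):
        if t.requires_grad:
            t._accumulate(g[seg])

    return Tensor._make(out_data, (t,), bw)


def diagonal(t: Tensor) -> Tensor:
    """Main diagonal of a square matrix."""

    def bw(g):
        if t.requires_grad:
            acc = np.zeros_like(t.data)
            np.fill_diagonal(acc, g)
            t._accumulate(acc)

    return Tensor._make(np.diagonal(t.data).copy(), (t,), bw)


def concat_rows(tensors: Iterable[Tensor]) -> Tensor:
    ts = list(tensors)
    sizes = [t.data.shape[0] for t in ts]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offs[:-1], offs[1:]):
            if t.requires_grad:
                t._accumulate(g[a:b])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=0), ts, bw)


class Adam:
    """Adaptive-moment gradient descent over a list of Tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def add_param(self, p: Tensor) -> None:
        self.params.append(p)
        self.m.append(np.zeros_like(p.data))
        self.v.append(np.zeros_like(p.data))

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
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
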