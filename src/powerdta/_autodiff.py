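"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The affinity network is small enough (a few GCN blocks, a 1-D CNN and a
three-layer fusion head) that a tape of NumPy primitives is sufficient:
every operation records its parents and a closure that accumulates the
upstream gradient into them.  Everything is float64; tensors are kept
2-D throughout the model (vectors travel as 1xM row matrices) so that
matmul gradients never need rank-dependent special cases.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "add", "sub", "mul", "matmul", "relu", "square",
           "mean", "amax_rows", "hstack", "gather_rows", "backward", "Adam"]


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    @property
    def shape(self):
        return self.data.shape

    def item(self) -> float:
        return float(self.data.reshape(-1)[0])

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], bwd) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = bwd
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient over the axes that broadcasting expanded."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g, b.data.shape)

    return _node(out_data, (a, b), bwd)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g, a.data.shape)
        if b.requires_grad:
            b.grad -= _unbroadcast(g, b.data.shape)

    return _node(out_data, (a, b), bwd)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += _unbroadcast(g * b.data, a.data.shape)
        if b.requires_grad:
            b.grad += _unbroadcast(g * a.data, b.data.shape)

    return _node(out_data, (a, b), bwd)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul expects 2-D operands")
    if a.data.shape[1] != b.data.shape[0]:
        raise ValueError(
            f"matmul dimension mismatch: {a.data.shape} @ {b.data.shape}")
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            a.grad += g @ b.data.T
        if b.requires_grad:
            b.grad += a.data.T @ g

    return _node(out_data, (a, b), bwd)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    out_data = a.data * mask

    def bwd(g):
        if a.requires_grad:
            a.grad += g * mask

    return _node(out_data, (a,), bwd)


def square(a) -> Tensor:
    a = _as_tensor(a)
    out_data = a.data ** 2

    def bwd(g):
        if a.requires_grad:
            a.grad += g * 2.0 * a.data

    return _node(out_data, (a,), bwd)


def mean(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size
    out_data = a.data.mean()

    def bwd(g):
        if a.requires_grad:
            a.grad += np.full_like(a.data, float(g) / n)

    return _node(out_data, (a,), bwd)


def amax_rows(a) -> Tensor:
    """Global max pooling: column-wise maximum over rows, result 1xM.

    Gradient routes to the first row attaining the maximum in each column.
    """
    a = _as_tensor(a)
    idx = np.argmax(a.data, axis=0)
    cols = np.arange(a.data.shape[1])
    out_data = a.data[idx, cols][None, :]

    def bwd(g):
        if a.requires_grad:
            contrib = np.zeros_like(a.data)
            contrib[idx, cols] = g[0]
            a.grad += contrib

    return _node(out_data, (a,), bwd)


def hstack(tensors: Sequence[Tensor]) -> Tensor:
    """Concatenate 1xM row matrices along axis 1."""
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=1)
    offsets = np.cumsum([0] + [t.data.shape[1] for t in tensors])

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                t.grad += g[:, lo:hi]

    return _node(out_data, tensors, bwd)


def gather_rows(a, index: np.ndarray) -> Tensor:
    """im2col gather: rows of a (L, C) matrix indexed by an (L_out, K)
    integer array, flattened to (L_out, K*C) patches for convolution."""
    a = _as_tensor(a)
    n_out, k = index.shape
    c = a.data.shape[1]
    out_data = a.data[index].reshape(n_out, k * c)

    def bwd(g):
        if a.requires_grad:
            np.add.at(a.grad, index, g.reshape(n_out, k, c))

    return _node(out_data, (a,), bwd)


def backward(out: Tensor) -> None:
    """Run reverse-mode accumulation from a scalar (or any) output."""
    topo: list[Tensor] = []
    seen: set[int] = set()

    def visit(t: Tensor) -> None:
        if id(t) in seen or not t.requires_grad:
            return
        seen.add(id(t))
        for p in t._parents:
            visit(p)
        topo.append(t)

    visit(out)
    for t in topo:
        t.grad = np.zeros_like(t.data)
    if out.grad is None:
        out.grad = np.ones_like(out.data)
    else:
        out.grad = out.grad + np.ones_like(out.data)
    for t in reversed(topo):
        if t._backward is not None:
            t._backward(t.grad)


class Adam:
    """Adaptive-moment gradient descent over a dict of parameter tensors."""

    def __init__(self, params: dict[str, Tensor], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = np.zeros_like(p.data)

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self._m[k] = self.b1 * self._m[k] + (1 - self.b1) * g
            v = self._v[k] = self.b2 * self._v[k] + (1 - self.b2) * g * g
            m_hat = m / (1 - self.b1 ** self.t)
            v_hat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
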