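"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine in the micrograd style, array-valued: each op records its
parents and a closure that pushes the incoming gradient back to them.  It
implements exactly the operations the sequence classifiers need — elementwise
arithmetic with broadcasting, matrix products, the sigmoid/tanh/ReLU
nonlinearities, reductions, slicing and stacking — in float64, single
threaded, so repeated passes are bitwise reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "sigmoid",
    "tanh",
    "relu",
    "log",
    "clip",
    "tsum",
    "tmean",
    "getitem",
    "stack",
    "softmax_masked",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` (a broadcast result) back to ``shape``."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "_parents", "_backward")

    def __init__(self, data, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into every ancestor."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack_ = [self]
        # iterative post-order DFS
        while stack_:
            node = stack_[-1]
            if id(node) in seen:
                stack_.pop()
                continue
            unvisited = [p for p in node._parents if id(p) not in seen]
            if unvisited:
                stack_.extend(unvisited)
            else:
                seen.add(id(node))
                topo.append(node)
                stack_.pop()

        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # Convenience operators (constants are wrapped on the fly).
    def __add__(self, other):
        return add(self, _wrap(other))

    def __sub__(self, other):
        return sub(self, _wrap(other))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    def __rmul__(self, other):
        return mul(_wrap(other), self)

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, idx):
        return getitem(self, idx)


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, (a, b))

    def bw(g):
        a.grad += _sum_to_shape(g, a.data.shape)
        b.grad += _sum_to_shape(g, b.data.shape)

    out._backward = bw
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, (a, b))

    def bw(g):
        a.grad += _sum_to_shape(g, a.data.shape)
        b.grad -= _sum_to_shape(g, b.data.shape)

    out._backward = bw
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, (a, b))

    def bw(g):
        a.grad += _sum_to_shape(g * b.data, a.data.shape)
        b.grad += _sum_to_shape(g * a.data, b.data.shape)

    out._backward = bw
    return out


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data @ b.data, (a, b))

    def bw(g):
        a.grad += _sum_to_shape(g @ np.swapaxes(b.data, -1, -2), a.data.shape)
        b.grad += _sum_to_shape(np.swapaxes(a.data, -1, -2) @ g, b.data.shape)

    out._backward = bw
    return out


def sigmoid(a: Tensor) -> Tensor:
    # numerically stable logistic
    s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-a.data)),
                 np.exp(a.data) / (1.0 + np.exp(a.data)))
    out = Tensor(s, (a,))

    def bw(g):
        a.grad += g * s * (1.0 - s)

    out._backward = bw
    return out


def tanh(a: Tensor) -> Tensor:
    t = np.tanh(a.data)
    out = Tensor(t, (a,))

    def bw(g):
        a.grad += g * (1.0 - t * t)

    out._backward = bw
    return out


def relu(a: Tensor) -> Tensor:
    out = Tensor(np.maximum(a.data, 0.0), (a,))

    def bw(g):
        a.grad += g * (a.data > 0)

    out._backward = bw
    return out


def log(a: Tensor) -> Tensor:
    out = Tensor(np.log(a.data), (a,))

    def bw(g):
        a.grad += g / a.data

    out._backward = bw
    return out


def clip(a: Tensor, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes through only inside the open interval."""
    out = Tensor(np.clip(a.data, lo, hi), (a,))

    def bw(g):
        a.grad += g * ((a.data > lo) & (a.data < hi))

    out._backward = bw
    return out


def tsum(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    out = Tensor(a.data.sum(axis=axis, keepdims=keepdims), (a,))

    def bw(g):
        if axis is None:
            a.grad += np.broadcast_to(g, a.data.shape)
        else:
            if not keepdims:
                g = np.expand_dims(g, axis)
            a.grad += np.broadcast_to(g, a.data.shape)

    out._backward = bw
    return out


def tmean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    n = a.data.size if axis is None else a.data.shape[axis]
    return mul(tsum(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def getitem(a: Tensor, idx) -> Tensor:
    out = Tensor(a.data[idx], (a,))

    def bw(g):
        np.add.at(a.grad, idx, g)

    out._backward = bw
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out = Tensor(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))

    def bw(g):
        pieces = np.split(g, len(tensors), axis=axis)
        for t, piece in zip(tensors, pieces):
            t.grad += np.squeeze(piece, axis=axis)

    out._backward = bw
    return out


def softmax_masked(scores: Tensor, mask: np.ndarray, axis: int = -1) -> Tensor:
    """Softmax over ``axis`` restricted to positions where ``mask`` is True.

    Invalid positions receive exactly zero weight; every row must contain at
    least one valid position.  The shift by the (stop-gradient) row maximum is
    the usual stabilisation and does not change the derivative, since softmax
    is shift-invariant.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=axis).all():
        raise ValueError("softmax_masked: some row has no valid position")
    neg = np.where(mask, 0.0, -1e30)
    shifted = add(scores, Tensor(neg))
    mx = np.max(shifted.data, axis=axis, keepdims=True)
    e_data = np.exp(shifted.data - mx) * mask

    e = Tensor(e_data, (shifted,))

    def bw_e(g):
        shifted.grad += g * e_data

    e._backward = bw_e

    denom = tsum(e, axis=axis, keepdims=True)
    inv = Tensor(1.0 / denom.data, (denom,))

    def bw_inv(g):
        denom.grad += -g / (denom.data ** 2)

    inv._backward = bw_inv
    return mul(e, inv)
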