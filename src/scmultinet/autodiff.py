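"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the embedding autoencoders and the
heterogeneous graph transformer need: +, -, *, /, matmul, transpose, relu,
exp, log, power, reductions, concatenation, slicing and a numerically stable
masked log-softmax.  Gradients for broadcast operands are summed back to the
operand shape.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` over axes that were broadcast from `shape`."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    # -- graph bookkeeping ---------------------------------------------------

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- ops -----------------------------------------------------------------

    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data + other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))
            out._backward = bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data * other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))
            out._backward = bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        return self * other ** -1.0

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                self._accumulate(g * p * self.data ** (p - 1.0))
            out._backward = bwd
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def bwd(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)
            out._backward = bwd
        return out

    __matmul__ = matmul

    @property
    def T(self) -> "Tensor":
        out = Tensor(self.data.T, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.T)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), self.requires_grad)
        if out.requires_grad:
            mask = (self.data > 0).astype(float)
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * out.data)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                if axis is None:
                    self._accumulate(np.broadcast_to(g, self.shape).copy())
                else:
                    gg = g if keepdims else np.expand_dims(g, axis)
                    self._accumulate(np.broadcast_to(gg, self.shape).copy())
            out._backward = bwd
        return out

    def mean(self) -> "Tensor":
        return self.sum() * (1.0 / self.data.size)

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def bwd(g):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bwd
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)
        out._backward = bwd
    return out


def masked_log_softmax(x: Tensor, mask: np.ndarray, axis: int = 0) -> Tensor:
    """log-softmax of `x` along `axis`, restricted to positions where
    ``mask`` is True; masked positions return -inf replaced by a large
    negative constant (their softmax weight is exactly 0 in forward/grad).
    """
    NEG = -1e30
    masked = x * mask + Tensor(np.where(mask, 0.0, NEG))
    mx = np.max(masked.data, axis=axis, keepdims=True)  # constant shift
    shifted = masked - Tensor(mx)
    lse = shifted.exp().sum(axis=axis, keepdims=True).log()
    return shifted - lse


def softmax_np(x: np.ndarray, axis: int = 0) -> np.ndarray:
    mx = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - mx)
    return e / e.sum(axis=axis, keepdims=True)


class Adam:
    """Adam optimizer over a list of parameter Tensors (deterministic)."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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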