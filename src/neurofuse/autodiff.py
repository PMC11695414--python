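"""Minimal reverse-mode automatic differentiation over numpy arrays.

The model in :mod:`neurofuse.model` is small enough that a dependency-free
tape-based engine is preferable to pulling in a deep-learning framework.
Only the operations the model actually uses are implemented; every op's
gradient is exercised by finite-difference checks in the test suite.

Conventions
-----------
* ``Tensor.data`` is always a ``float64`` ndarray; broadcasting follows
  numpy rules, and gradients of broadcast operands are summed back to the
  operand's shape.
* ``backward()`` may only be called on scalar tensors.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy.special import erf

__all__ = ["Tensor", "parameter", "constant"]

_INV_SQRT2 = 1.0 / np.sqrt(2.0)
_INV_SQRT2PI = 1.0 / np.sqrt(2.0 * np.pi)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over axes that were broadcast to reach ``grad.shape``."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward_fn: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward_fn

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- graph traversal ------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data + other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor(out_data, parents=(self, other), backward_fn=bw)

    __radd__ = __add__

    def __neg__(self) -> "Tensor":
        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        return Tensor(-self.data, parents=(self,), backward_fn=bw)

    def __sub__(self, other) -> "Tensor":
        return self + (-self._lift(other))

    def __rsub__(self, other) -> "Tensor":
        return self._lift(other) + (-self)

    def __mul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data * other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor(out_data, parents=(self, other), backward_fn=bw)

    __rmul__ = __mul__

    def __truediv__(self, other) -> "Tensor":
        other = self._lift(other)
        return self * other ** -1.0

    def __pow__(self, exponent: float) -> "Tensor":
        out_data = self.data ** exponent

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1.0))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def __matmul__(self, other) -> "Tensor":
        other = self._lift(other)
        out_data = self.data @ other.data

        def bw(g):
            if self.requires_grad:
                self._accumulate(
                    _unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape)
                )
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape)
                )

        return Tensor(out_data, parents=(self, other), backward_fn=bw)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape
        out_data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(old))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out_data = np.swapaxes(self.data, a, b)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.swapaxes(g, a, b))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def __getitem__(self, idx) -> "Tensor":
        out_data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(gg, self.shape).copy())

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        if axis is None:
            n = self.data.size
        else:
            axes = (axis,) if isinstance(axis, int) else tuple(axis)
            n = int(np.prod([self.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- nonlinearities -------------------------------------------------------
    def exp(self) -> "Tensor":
        out_data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def log(self) -> "Tensor":
        out_data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def tanh(self) -> "Tensor":
        out_data = np.tanh(self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (1.0 - out_data ** 2))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def gelu(self) -> "Tensor":
        """Exact (erf-based) GELU."""
        cdf = 0.5 * (1.0 + erf(self.data * _INV_SQRT2))
        out_data = self.data * cdf

        def bw(g):
            if self.requires_grad:
                pdf = _INV_SQRT2PI * np.exp(-0.5 * self.data ** 2)
                self._accumulate(g * (cdf + self.data * pdf))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def clamp_min(self, lo: float) -> "Tensor":
        out_data = np.maximum(self.data, lo)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * (self.data > lo))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def softmax(self, axis: int = -1) -> "Tensor":
        """Numerically stable softmax along ``axis``."""
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=axis, keepdims=True)
                self._accumulate(out_data * (g - dot))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def masked_fill(self, mask: np.ndarray, value: float) -> "Tensor":
        """Set entries where ``mask`` is True to ``value`` (no gradient there)."""
        out_data = np.where(mask, value, self.data)

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.where(mask, 0.0, g))

        return Tensor(out_data, parents=(self,), backward_fn=bw)

    def dropout(self, p: float, rng: np.random.Generator) -> "Tensor":
        """Inverted dropout; identity when p == 0."""
        if p <= 0.0:
            return self
        keep = (rng.random(self.shape) >= p).astype(np.float64) / (1.0 - p)

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * keep)

        return Tensor(self.data * keep, parents=(self,), backward_fn=bw)

    # -- structured ops -------------------------------------------------------
    def conv1d_same(self, weight: "Tensor", bias: "Tensor") -> "Tensor":
        """1-D convolution along axis -2 with zero same-padding, stride 1.

        ``self``: (..., T, d); ``weight``: (K, d, d_out) with K odd;
        ``bias``: (d_out,). Output: (..., T, d_out).
        """
        K, d, d_out = weight.shape
        if K % 2 != 1:
            raise ValueError("conv kernel width must be odd")
        T = self.shape[-2]
        half = K // 2
        pad = [(0, 0)] * (self.ndim - 2) + [(half, half), (0, 0)]
        xp = np.pad(self.data, pad)
        out_data = np.broadcast_to(bias.data, self.shape[:-2] + (T, d_out)).copy()
        for k in range(K):
            out_data += xp[..., k : k + T, :] @ weight.data[k]

        def bw(g):
            if self.requires_grad:
                gxp = np.zeros_like(xp)
                for k in range(K):
                    gxp[..., k : k + T, :] += g @ weight.data[k].T
                self._accumulate(gxp[..., half : half + T, :])
            if weight.requires_grad:
                gw = np.zeros_like(weight.data)
                for k in range(K):
                    win = xp[..., k : k + T, :].reshape(-1, d)
                    gw[k] = win.T @ g.reshape(-1, d_out)
                weight._accumulate(gw)
            if bias.requires_grad:
                bias._accumulate(g.reshape(-1, d_out).sum(axis=0))

        return Tensor(out_data, parents=(self, weight, bias), backward_fn=bw)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def constant(data) -> Tensor:
    return Tensor(data)
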