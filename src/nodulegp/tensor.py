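"""Minimal reverse-mode automatic differentiation over numpy arrays.

The growth-predictive adversarial model in :mod:`nodulegp.gpwgan` trains small
convolutional networks on 64x64 CT nodule patches. This module supplies the
handful of differentiable primitives those networks need (dense/convolution
layers, pointwise nonlinearities, reductions, concatenation, nearest-neighbour
upsampling) with a tape-based backward pass.

Only first-order gradients are supported. The WGAN gradient-penalty term,
which formally requires differentiating through an input gradient, is handled
in :mod:`nodulegp.gpwgan.models` by exploiting the critic's piecewise
linearity (the input gradient is rebuilt as an explicit transpose pass with
activation masks held constant), so no second-order machinery is needed.

Convolutions use im2col + BLAS matmul; the adjoint (transposed) convolution is
exposed as a first-class primitive because the critic's input-gradient pass is
built from it.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv2d",
    "conv_transpose2d",
    "leaky_relu",
    "relu",
    "sigmoid",
    "upsample_nearest",
]


def _sum_to_shape(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    # sum out prepended axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array plus gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None

    # ---------------------------------------------------------------- basic
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        # topological order
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ----------------------------------------------------------- arithmetic
    def __add__(self, other):
        return _binop(self, other, np.add,
                      lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binop(self, other, np.subtract,
                      lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return as_tensor(other) - self

    def __mul__(self, other):
        return _binop(self, other, np.multiply,
                      lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binop(self, other, np.divide,
                      lambda g, a, b: g / b,
                      lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __neg__(self):
        return _unop(self, np.negative, lambda g, x: -g)

    def __pow__(self, p: float):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents are supported")
        return _unop(self, lambda x: np.power(x, p),
                     lambda g, x: g * p * np.power(x, p - 1))

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor(self.data @ other.data,
                     self.requires_grad or other.requires_grad)
        if out.requires_grad:
            a, b = self, other

            def bwd(g):
                if a.requires_grad:
                    a._accumulate(g @ b.data.T)
                if b.requires_grad:
                    b._accumulate(a.data.T @ g)

            out._parents = (a, b)
            out._backward = bwd
        return out

    # ----------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims),
                     self.requires_grad)
        if out.requires_grad:
            src = self
            shape = self.data.shape

            def bwd(g):
                if not keepdims and axis is not None:
                    g = np.expand_dims(g, axis)
                src._accumulate(np.broadcast_to(g, shape))

            out._parents = (src,)
            out._backward = bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor(self.data.reshape(shape), self.requires_grad)
        if out.requires_grad:
            src = self
            orig = self.data.shape
            out._parents = (src,)
            out._backward = lambda g: src._accumulate(g.reshape(orig))
        return out

    # ------------------------------------------------------------ pointwise
    def exp(self) -> "Tensor":
        return _unop(self, np.exp, lambda g, x: g * np.exp(x))

    def sqrt(self) -> "Tensor":
        return _unop(self, np.sqrt, lambda g, x: g * 0.5 / np.sqrt(x))

    def abs(self) -> "Tensor":
        return _unop(self, np.abs, lambda g, x: g * np.sign(x))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _unop(x: Tensor, f, df) -> Tensor:
    out = Tensor(f(x.data), x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(df(g, x.data))
    return out


def _binop(a, b, f, dfa, dfb) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = Tensor(f(a.data, b.data), a.requires_grad or b.requires_grad)
    if out.requires_grad:

        def bwd(g):
            if a.requires_grad:
                a._accumulate(_sum_to_shape(dfa(g, a.data, b.data), a.data.shape))
            if b.requires_grad:
                b._accumulate(_sum_to_shape(dfb(g, a.data, b.data), b.data.shape))

        out._parents = (a, b)
        out._backward = bwd
    return out


# --------------------------------------------------------------- activations
def relu(x: Tensor) -> Tensor:
    return _unop(x, lambda v: np.maximum(v, 0), lambda g, v: g * (v > 0))


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    return _unop(x, lambda v: np.where(v > 0, v, alpha * v),
                 lambda g, v: g * np.where(v > 0, 1.0, alpha))


def sigmoid(x: Tensor) -> Tensor:
    def f(v):
        return 1.0 / (1.0 + np.exp(-v))

    return _unop(x, f, lambda g, v: g * f(v) * (1.0 - f(v)))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 any(t.requires_grad for t in tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._parents = tuple(tensors)
        out._backward = bwd
    return out


# -------------------------------------------------------------- convolution
def _conv_out_hw(h: int, w: int, kh: int, kw: int, stride: int, pad: int):
    return (h + 2 * pad - kh) // stride + 1, (w + 2 * pad - kw) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """(B,C,H,W) -> cols (B*Ho*Wo, C*kh*kw) plus output spatial dims."""
    b, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    ho, wo = v.shape[2], v.shape[3]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(b * ho * wo, c * kh * kw), ho, wo


def _conv_forward(x: np.ndarray, w: np.ndarray, stride: int, pad: int):
    b = x.shape[0]
    co, ci, kh, kw = w.shape
    cols, ho, wo = _im2col(x, kh, kw, stride, pad)
    out = cols @ w.reshape(co, -1).T
    return out.reshape(b, ho, wo, co).transpose(0, 3, 1, 2)


def _conv_input_grad(gout: np.ndarray, w: np.ndarray, stride: int, pad: int,
                     in_hw: tuple[int, int]) -> np.ndarray:
    """Adjoint of _conv_forward with respect to its input."""
    b, co, ho, wo = gout.shape
    _, ci, kh, kw = w.shape
    h, wd = in_hw
    gpad = np.zeros((b, ci, h + 2 * pad, wd + 2 * pad), dtype=gout.dtype)
    gmat = gout.transpose(0, 2, 3, 1)  # (B,Ho,Wo,Co)
    for i in range(kh):
        for j in range(kw):
            # (B,Ho,Wo,Co) @ (Co,Ci) -> (B,Ho,Wo,Ci)
            contrib = gmat @ w[:, :, i, j]
            gpad[:, :, i:i + ho * stride:stride,
                 j:j + wo * stride:stride] += contrib.transpose(0, 3, 1, 2)
    if pad:
        return gpad[:, :, pad:-pad, pad:-pad]
    return gpad


def _conv_weight_grad(x: np.ndarray, gout: np.ndarray, kh: int, kw: int,
                      stride: int, pad: int) -> np.ndarray:
    b, co, ho, wo = gout.shape
    cols, _, _ = _im2col(x, kh, kw, stride, pad)
    gmat = gout.transpose(0, 2, 3, 1).reshape(b * ho * wo, co)
    gw = gmat.T @ cols  # (Co, C*kh*kw)
    return gw.reshape(co, x.shape[1], kh, kw)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 1) -> Tensor:
    """2D convolution (cross-correlation), NCHW, weight (Co,Ci,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    out_data = _conv_forward(x.data, w.data, stride, pad)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(out_data, req)
    if req:
        in_hw = x.data.shape[2:]
        kh, kw = w.data.shape[2:]

        def bwd(g):
            if x.requires_grad:
                x._accumulate(_conv_input_grad(g, w.data, stride, pad, in_hw))
            if w.requires_grad:
                w._accumulate(_conv_weight_grad(x.data, g, kh, kw, stride, pad))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))

        out._parents = tuple(t for t in (x, w, b) if t is not None)
        out._backward = bwd
    return out


def conv_transpose2d(x: Tensor, w: Tensor, stride: int, pad: int,
                     out_hw: tuple[int, int]) -> Tensor:
    """Adjoint of :func:`conv2d`: maps (B,Co,Ho,Wo) back to (B,Ci,H,W).

    Weight layout matches the forward convolution it transposes. Used to build
    the critic's input-gradient pass as an explicit differentiable graph.
    """
    x, w = as_tensor(x), as_tensor(w)
    out = Tensor(_conv_input_grad(x.data, w.data, stride, pad, out_hw),
                 x.requires_grad or w.requires_grad)
    if out.requires_grad:
        kh, kw = w.data.shape[2:]

        def bwd(g):
            if x.requires_grad:
                x._accumulate(_conv_forward(g, w.data, stride, pad))
            if w.requires_grad:
                # d/dw of adjoint: same as conv weight grad with roles swapped
                w._accumulate(_conv_weight_grad(g, x.data, kh, kw, stride, pad))

        out._parents = (x, w)
        out._backward = bwd
    return out


def upsample_nearest(x: Tensor, factor: int = 2) -> Tensor:
    """Nearest-neighbour spatial upsampling for NCHW tensors."""
    x = as_tensor(x)
    out = Tensor(x.data.repeat(factor, axis=2).repeat(factor, axis=3),
                 x.requires_grad)
    if out.requires_grad:
        b, c, h, w = x.data.shape

        def bwd(g):
            g = g.reshape(b, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accumulate(g)

        out._parents = (x,)
        out._backward = bwd
    return out
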