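"""A compact reverse-mode automatic-differentiation engine on NumPy arrays.

Implements exactly the operator set the detector needs: 2-D convolution
(grouped/depthwise, arbitrary stride and padding) via im2col + GEMM, batch
normalization, SiLU/sigmoid, nearest-neighbour upsampling, max pooling,
concatenation/slicing, broadcasting arithmetic, reductions, softmax-family
ops and the two classification losses.  Forward passes run in float32; a
module-level ``no_grad`` switch gives a plain-NumPy fast path for inference.

The engine favours clarity over generality: every backward rule is written
by hand and checked against central finite differences in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = ["Tensor", "Parameter", "no_grad", "is_grad_enabled", "concat"]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _as_array(x) -> np.ndarray:
    if isinstance(x, Tensor):
        return x.data
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: Tuple["Tensor", ...] = ()

    # ---- bookkeeping -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t: "Tensor"):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                # free intermediate grads? keep: training graphs are small
                pass

    def __repr__(self) -> str:
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ---- graph helper ------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = is_grad_enabled() and any(p.requires_grad for p in parents)
        out = Tensor(data)
        if req:
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad or p._parents)
            out._backward = backward
        return out

    # ---- arithmetic --------------------------------------------------
    def __add__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data + o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g, o.data.shape))

        return Tensor._make(data, (self, o), bw)

    __radd__ = __add__

    def __neg__(self):
        data = -self.data

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        return Tensor._make(data, (self,), bw)

    def __sub__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data - o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g, o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def __rsub__(self, other):
        return Tensor(other) - self

    def __mul__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data * o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * self.data, o.data.shape))

        return Tensor._make(data, (self, o), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = self.data / o.data

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / o.data, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(-g * self.data / (o.data * o.data), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def __rtruediv__(self, other):
        return Tensor(other) / self

    def __pow__(self, p: float):
        data = self.data ** p

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return Tensor._make(data, (self,), bw)

    # ---- shaping -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        data = self.data.reshape(shape)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return Tensor._make(data, (self,), bw)

    def transpose(self, *axes):
        data = self.data.transpose(axes)
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return Tensor._make(data, (self,), bw)

    def __getitem__(self, idx):
        data = self.data[idx]

        def bw(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                np.add.at(gx, idx, g)
                self._accum(gx)

        return Tensor._make(data, (self,), bw)

    # ---- reductions --------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        data = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape).astype(np.float32))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, shape).astype(np.float32))

        return Tensor._make(data, (self,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ---- elementwise nonlinearities ---------------------------------
    def exp(self):
        data = np.exp(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data)

        return Tensor._make(data, (self,), bw)

    def log(self):
        data = np.log(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return Tensor._make(data, (self,), bw)

    def sqrt(self):
        return self ** 0.5

    def arctan(self):
        data = np.arctan(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data * self.data))

        return Tensor._make(data, (self,), bw)

    def sigmoid(self):
        data = _sigmoid(self.data)

        def bw(g):
            if self.requires_grad:
                self._accum(g * data * (1.0 - data))

        return Tensor._make(data, (self,), bw)

    def silu(self):
        s = _sigmoid(self.data)
        data = self.data * s

        def bw(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return Tensor._make(data, (self,), bw)

    def clip(self, lo: float, hi: float):
        data = np.clip(self.data, lo, hi)

        def bw(g):
            if self.requires_grad:
                self._accum(g * ((self.data >= lo) & (self.data <= hi)))

        return Tensor._make(data, (self,), bw)

    def maximum(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = np.maximum(self.data, o.data)

        def bw(g):
            # ties split the gradient evenly (keeps symmetric expressions
            # like IoU stationary at exact coincidence)
            m = (self.data > o.data) + 0.5 * (self.data == o.data)
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (1.0 - m), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    def minimum(self, other):
        o = other if isinstance(other, Tensor) else Tensor(other)
        data = np.minimum(self.data, o.data)

        def bw(g):
            m = (self.data < o.data) + 0.5 * (self.data == o.data)
            if self.requires_grad:
                self._accum(_unbroadcast(g * m, self.data.shape))
            if o.requires_grad:
                o._accum(_unbroadcast(g * (1.0 - m), o.data.shape))

        return Tensor._make(data, (self, o), bw)

    # ---- softmax family ---------------------------------------------
    def softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        data = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            if self.requires_grad:
                dot = (g * data).sum(axis=axis, keepdims=True)
                self._accum(data * (g - dot))

        return Tensor._make(data, (self,), bw)

    def log_softmax(self, axis: int = -1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        data = z - lse
        sm = np.exp(data)

        def bw(g):
            if self.requires_grad:
                self._accum(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(data, (self,), bw)

    def bce_with_logits(self, targets: np.ndarray):
        """Elementwise binary cross-entropy on logits; targets are constants."""
        t = np.asarray(targets, dtype=np.float32)
        x = self.data
        data = np.maximum(x, 0) - x * t + np.log1p(np.exp(-np.abs(x)))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (_sigmoid(x) - t))

        return Tensor._make(data, (self,), bw)

    # ---- structured ops ----------------------------------------------
    def conv2d(self, weight: "Tensor", bias: Optional["Tensor"] = None,
               stride: int = 1, padding: int = 0, groups: int = 1) -> "Tensor":
        return _conv2d(self, weight, bias, stride, padding, groups)

    def maxpool2d(self, kernel: int, stride: int = 1, padding: int = 0) -> "Tensor":
        return _maxpool2d(self, kernel, stride, padding)

    def upsample2x(self) -> "Tensor":
        n, c, h, w = self.data.shape
        data = self.data.repeat(2, axis=2).repeat(2, axis=3)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))

        return Tensor._make(data, (self,), bw)


class Parameter(Tensor):
    """A trainable tensor (weight matrix, norm scale, ...)."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, ts, bw)


# ---------------------------------------------------------------------
# convolution via im2col + batched GEMM
# ---------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int, groups: int):
    """Return column matrix (N, g, Cg*k*k, OH*OW) plus output spatial size."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]            # (N, C, OH, OW, k, k)
    col = win.transpose(0, 1, 4, 5, 2, 3)          # (N, C, k, k, OH, OW)
    col = np.ascontiguousarray(col).reshape(n, groups, (c // groups) * k * k, oh * ow)
    return col, oh, ow


def _col2im(dcol: np.ndarray, x_shape, k: int, stride: int, pad: int, groups: int):
    """Scatter-add column gradients back to input layout."""
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    l = dcol.shape[-1]
    oh = (h + 2 * pad - k) // stride + 1
    ow = l // oh
    dcol = dcol.reshape(n, c, k, k, oh, ow)
    dx = np.zeros((n, c, hp, wp), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += dcol[:, :, i, j]
    if pad:
        dx = dx[:, :, pad:pad + h, pad:pad + w]
    return dx


def _conv2d(x: Tensor, weight: Tensor, bias: Optional[Tensor],
            stride: int, padding: int, groups: int) -> Tensor:
    n, c1, h, w = x.data.shape
    c2, c1g, kh, kw = weight.data.shape
    if kh != kw:
        raise ValueError("only square kernels are supported")
    if c1 % groups or c2 % groups or c1g != c1 // groups:
        raise ValueError(
            f"channel/group mismatch: input {c1} channels, weight expects "
            f"{c1g}*{groups} input channels and {c2} outputs")
    k = kh
    col, oh, ow = _im2col(x.data, k, stride, padding, groups)   # (N,g,K,L)
    wmat = weight.data.reshape(groups, c2 // groups, c1g * k * k)  # (g,C2g,K)
    out = np.matmul(wmat, col)                                  # (N,g,C2g,L)
    out = out.reshape(n, c2, oh, ow)
    if bias is not None:
        out = out + bias.data.reshape(1, c2, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gmat = g.reshape(n, groups, c2 // groups, oh * ow)       # (N,g,C2g,L)
        if weight.requires_grad:
            dw = np.matmul(gmat, col.transpose(0, 1, 3, 2)).sum(axis=0)  # (g,C2g,K)
            weight._accum(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcol = np.matmul(wmat.transpose(0, 2, 1), gmat)      # (N,g,K,L)
            x._accum(_col2im(dcol.reshape(n, c1 * k * k, oh * ow),
                             x.data.shape, k, stride, padding, groups))

    return Tensor._make(out, parents, bw)


def _maxpool2d(x: Tensor, k: int, stride: int, padding: int) -> Tensor:
    n, c, h, w = x.data.shape
    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                    constant_values=-np.inf)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                  # (N,C,OH,OW,k,k)
    oh, ow = win.shape[2], win.shape[3]
    flat = win.reshape(n, c, oh, ow, k * k)
    amax = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, amax[..., None], axis=-1)[..., 0]

    def bw(g):
        if not x.requires_grad:
            return
        hp, wp = h + 2 * padding, w + 2 * padding
        dx = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                m = (amax == i * k + j)
                dx[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += g * m
        if padding:
            dx = dx[:, :, padding:padding + h, padding:padding + w]
        x._accum(dx)

    return Tensor._make(np.ascontiguousarray(out), (x,), bw)
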