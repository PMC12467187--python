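"""Reverse-mode automatic differentiation over NumPy arrays.

A deliberately small tape-based engine providing exactly the operations the
detection head and training loop need: broadcast arithmetic, activations,
reductions, batched matmul, softmax, dense / depthwise 2-D convolution
(stride, padding, dilation), nearest-neighbour 2x upsampling and a
numerically stable binary cross-entropy on logits.

Gradients accumulate into ``Tensor.grad`` on :meth:`Tensor.backward`.
Computation keeps the dtype of its inputs (float32 by default; tests use
float64 for finite-difference checks).
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "tensor",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "exp",
    "log",
    "sigmoid",
    "silu",
    "maximum",
    "minimum",
    "clip",
    "tsum",
    "tmean",
    "reshape",
    "transpose",
    "matmul",
    "softmax",
    "conv2d",
    "dwconv2d",
    "upsample2",
    "bce_with_logits",
]

_FLOATS = (np.float32, np.float64)


class Tensor:
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, dtype=None):
        arr = np.asarray(data, dtype=dtype)
        if arr.dtype.type not in _FLOATS:
            arr = arr.astype(np.float32)
        self.data: np.ndarray = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- graph ---------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node; ``grad`` defaults to ones (scalar)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        for node in topo:
            node.grad = np.zeros_like(node.data)
        self.grad = self.grad + np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return sub(tensor(other), self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(tensor(other), self)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)


def tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    if isinstance(x, (int, float)):
        # scalar constants as float32 so they never promote a float32 graph
        return Tensor(np.float32(x))
    return Tensor(x)


def _pair(v) -> tuple[int, int]:
    if isinstance(v, (tuple, list)):
        return int(v[0]), int(v[1])
    return int(v), int(v)


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def _acc(t: Tensor, g: np.ndarray) -> None:
    if t.requires_grad and t.grad is not None:
        t.grad += g


def _node(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise arithmetic
# ---------------------------------------------------------------------------


def add(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data + b.data

    def bw(g):
        _acc(a, _unbroadcast(g, a.shape))
        _acc(b, _unbroadcast(g, b.shape))

    return _node(data, (a, b), bw)


def sub(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data - b.data

    def bw(g):
        _acc(a, _unbroadcast(g, a.shape))
        _acc(b, _unbroadcast(-g, b.shape))

    return _node(data, (a, b), bw)


def mul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data * b.data

    def bw(g):
        _acc(a, _unbroadcast(g * b.data, a.shape))
        _acc(b, _unbroadcast(g * a.data, b.shape))

    return _node(data, (a, b), bw)


def div(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = a.data / b.data

    def bw(g):
        _acc(a, _unbroadcast(g / b.data, a.shape))
        _acc(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return _node(data, (a, b), bw)


def neg(a) -> Tensor:
    a = tensor(a)

    def bw(g):
        _acc(a, -g)

    return _node(-a.data, (a,), bw)


def exp(a) -> Tensor:
    a = tensor(a)
    data = np.exp(a.data)

    def bw(g):
        _acc(a, g * data)

    return _node(data, (a,), bw)


def log(a) -> Tensor:
    a = tensor(a)

    def bw(g):
        _acc(a, g / a.data)

    return _node(np.log(a.data), (a,), bw)


def sigmoid(a) -> Tensor:
    a = tensor(a)
    # stable sigmoid
    data = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-np.abs(a.data))),
                    np.exp(-np.abs(a.data)) / (1.0 + np.exp(-np.abs(a.data))))
    data = data.astype(a.dtype, copy=False)

    def bw(g):
        _acc(a, g * data * (1.0 - data))

    return _node(data, (a,), bw)


def silu(a) -> Tensor:
    a = tensor(a)
    e = np.exp(-np.abs(a.data))
    s = np.where(a.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    data = a.data * s

    def bw(g):
        _acc(a, g * (s + a.data * s * (1.0 - s)))

    return _node(data.astype(a.dtype, copy=False), (a,), bw)


def maximum(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    mask = a.data >= b.data  # ties route to the first argument

    def bw(g):
        _acc(a, _unbroadcast(g * mask, a.shape))
        _acc(b, _unbroadcast(g * ~mask, b.shape))

    return _node(np.maximum(a.data, b.data), (a, b), bw)


def minimum(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    mask = a.data <= b.data

    def bw(g):
        _acc(a, _unbroadcast(g * mask, a.shape))
        _acc(b, _unbroadcast(g * ~mask, b.shape))

    return _node(np.minimum(a.data, b.data), (a, b), bw)


def clip(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    out = tensor(a)
    if lo is not None:
        out = maximum(out, Tensor(np.asarray(lo, dtype=out.dtype)))
    if hi is not None:
        out = minimum(out, Tensor(np.asarray(hi, dtype=out.dtype)))
    return out


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------


def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bw(g):
        gg = np.asarray(g)
        if axis is not None and not keepdims:
            gg = np.expand_dims(gg, axis)
        _acc(a, np.broadcast_to(gg, a.shape).astype(a.dtype, copy=False))

    return _node(data, (a,), bw)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = 1
        for ax in axes:
            n *= a.shape[ax]
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def reshape(a, shape) -> Tensor:
    a = tensor(a)

    def bw(g):
        _acc(a, g.reshape(a.shape))

    return _node(a.data.reshape(shape), (a,), bw)


def transpose(a, axes) -> Tensor:
    a = tensor(a)
    inv = np.argsort(axes)

    def bw(g):
        _acc(a, np.transpose(g, inv))

    return _node(np.transpose(a.data, axes), (a,), bw)


# ---------------------------------------------------------------------------
# linear algebra / attention
# ---------------------------------------------------------------------------


def matmul(a, b) -> Tensor:
    a, b = tensor(a), tensor(b)
    data = np.matmul(a.data, b.data)

    def bw(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        _acc(a, _unbroadcast(ga, a.shape))
        _acc(b, _unbroadcast(gb, b.shape))

    return _node(data, (a, b), bw)


def softmax(a, axis: int = -1) -> Tensor:
    a = tensor(a)
    z = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        dot = (g * data).sum(axis=axis, keepdims=True)
        _acc(a, data * (g - dot))

    return _node(data, (a,), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------


def conv2d(x, w, stride=1, padding=0, dilation=1) -> Tensor:
    """Dense 2-D cross-correlation: x (B,Cin,H,W), w (Cout,Cin,kh,kw)."""
    x, w = tensor(x), tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw_ = _pair(dilation)
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError(f"conv2d channel mismatch: input {Cin} vs weight {Cin2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hout = (H + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    Wout = (W + 2 * pw - dw_ * (kw - 1) - 1) // sw + 1
    y = np.zeros((B, Cout, Hout, Wout), dtype=x.dtype)
    wd = w.data
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * dh: i * dh + sh * Hout: sh, j * dw_: j * dw_ + sw * Wout: sw]
            y += np.einsum("oc,bchw->bohw", wd[:, :, i, j], xs, optimize=True)

    def bw(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad and w.grad is not None:
                    xs = xp[:, :, i * dh: i * dh + sh * Hout: sh,
                            j * dw_: j * dw_ + sw * Wout: sw]
                    w.grad[:, :, i, j] += np.einsum("bohw,bchw->oc", g, xs, optimize=True)
                if x.requires_grad:
                    dxp[:, :, i * dh: i * dh + sh * Hout: sh,
                        j * dw_: j * dw_ + sw * Wout: sw] += np.einsum(
                        "oc,bohw->bchw", wd[:, :, i, j], g, optimize=True)
        if x.requires_grad:
            _acc(x, dxp[:, :, ph: ph + H, pw: pw + W])

    return _node(y, (x, w), bw)


def dwconv2d(x, w, padding=(0, 0), dilation=(1, 1)) -> Tensor:
    """Depthwise 2-D cross-correlation: x (B,C,H,W), w (C,kh,kw), stride 1."""
    x, w = tensor(x), tensor(w)
    ph, pw = _pair(padding)
    dh, dw_ = _pair(dilation)
    B, C, H, W = x.shape
    C2, kh, kw = w.shape
    if C != C2:
        raise ValueError(f"dwconv2d channel mismatch: input {C} vs weight {C2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    Hout = H + 2 * ph - dh * (kh - 1)
    Wout = W + 2 * pw - dw_ * (kw - 1)
    y = np.zeros((B, C, Hout, Wout), dtype=x.dtype)
    wd = w.data
    for i in range(kh):
        for j in range(kw):
            xs = xp[:, :, i * dh: i * dh + Hout, j * dw_: j * dw_ + Wout]
            y += wd[:, i, j][None, :, None, None] * xs

    def bw(g):
        if x.requires_grad:
            dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                if w.requires_grad and w.grad is not None:
                    xs = xp[:, :, i * dh: i * dh + Hout, j * dw_: j * dw_ + Wout]
                    w.grad[:, i, j] += np.einsum("bchw,bchw->c", g, xs, optimize=True)
                if x.requires_grad:
                    dxp[:, :, i * dh: i * dh + Hout, j * dw_: j * dw_ + Wout] += (
                        wd[:, i, j][None, :, None, None] * g)
        if x.requires_grad:
            _acc(x, dxp[:, :, ph: ph + H, pw: pw + W])

    return _node(y, (x, w), bw)


def pad2d(x, margin: int) -> Tensor:
    """Zero-pad the two trailing (spatial) axes of (B,C,H,W) symmetrically."""
    x = tensor(x)
    m = int(margin)
    data = np.pad(x.data, ((0, 0), (0, 0), (m, m), (m, m)))

    def bw(g):
        _acc(x, g[:, :, m: g.shape[2] - m, m: g.shape[3] - m])

    return _node(data, (x,), bw)


def upsample2(x) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling of (B,C,H,W)."""
    x = tensor(x)
    data = np.repeat(np.repeat(x.data, 2, axis=2), 2, axis=3)
    B, C, H, W = x.shape

    def bw(g):
        _acc(x, g.reshape(B, C, H, 2, W, 2).sum(axis=(3, 5)))

    return _node(data, (x,), bw)


def bce_with_logits(logits, targets) -> Tensor:
    """Elementwise binary cross-entropy on logits (stable form)."""
    x, t = tensor(logits), tensor(targets)
    xd = x.data
    data = np.maximum(xd, 0) - xd * t.data + np.log1p(np.exp(-np.abs(xd)))
    e = np.exp(-np.abs(xd))
    s = np.where(xd >= 0, 1.0 / (1.0 + e), e / (1.0 + e))

    def bw(g):
        _acc(x, g * (s - t.data))
        _acc(t, _unbroadcast(-g * xd, t.shape))

    return _node(data.astype(xd.dtype, copy=False), (x, t), bw)
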