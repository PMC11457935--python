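"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks on CPU; this module provides
the handful of differentiable operations those networks need (broadcasting
arithmetic, ReLU, |x|, reductions, concatenation, 2D convolution via im2col,
and fixed bilinear 2x upsampling). Everything is float64 for the sake of
bit-reproducibility and accurate finite-difference checks.

Tensors form an acyclic graph; ``Tensor.backward`` walks it in reverse
topological order and accumulates gradients into every node that has
``requires_grad`` set (directly or through a parent).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "narrow",
    "conv2d",
    "upsample2x_bilinear",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that numpy broadcasting expanded."""
    if grad.shape == shape:
        return grad
    # leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # axes of size 1 that were stretched
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @classmethod
    def _from_op(cls, data, parents, backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- basic info -----------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

        return Tensor._from_op(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._from_op(-a.data, (a,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)
        a, b = self, other

        def bw(g):
            return _unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)

        return Tensor._from_op(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * Tensor._lift(other) ** -1.0

    def __rtruediv__(self, other):
        return Tensor._lift(other) * self ** -1.0

    def __pow__(self, exponent: float):
        a = self
        c = float(exponent)
        data = a.data ** c

        def bw(g):
            return (g * c * a.data ** (c - 1.0),)

        return Tensor._from_op(data, (a,), bw)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        a = self
        keep = a.data > 0
        return Tensor._from_op(np.where(keep, a.data, 0.0), (a,), lambda g: (g * keep,))

    def abs(self):
        a = self
        sign = np.sign(a.data)  # subgradient 0 at 0
        return Tensor._from_op(np.abs(a.data), (a,), lambda g: (g * sign,))

    # -- reductions & reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, a.shape).copy(),)

        return Tensor._from_op(data, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[i] for i in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        a = self
        old = a.shape
        return Tensor._from_op(
            a.data.reshape(*shape), (a,), lambda g: (g.reshape(old),)
        )

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float64)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, g in zip(node._parents, node._backward(node.grad)):
                if not parent.requires_grad or g is None:
                    continue
                if parent.grad is None:
                    parent.grad = g
                else:
                    parent.grad = parent.grad + g


class Parameter(Tensor):
    """A leaf tensor holding trainable weights."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._from_op(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, bw
    )


def narrow(x: Tensor, axis: int, start: int, stop: int) -> Tensor:
    """Slice ``x`` along one axis; the gradient scatters back into place."""
    x = Tensor._lift(x)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(start, stop)
    sl = tuple(sl)

    def bw(g):
        out = np.zeros_like(x.data)
        out[sl] = g
        return (out,)

    return Tensor._from_op(x.data[sl], (x,), bw)


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: tuple[int, int]):
    ph, pw = pad
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    n, c, hp, wp = x.shape
    oh = (hp - kh) // stride + 1
    ow = (wp - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, oh, ow),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(cols), oh, ow, (hp, wp)


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int | tuple[int, int] = 0,
) -> Tensor:
    """2D convolution (cross-correlation), NCHW layout, weight (F, C, kh, kw)."""
    x = Tensor._lift(x)
    if x.ndim != 4:
        raise ValueError(f"conv2d expects NCHW input, got shape {x.shape}")
    pad = (padding, padding) if isinstance(padding, int) else tuple(padding)
    f, cin, kh, kw = weight.shape
    if x.shape[1] != cin:
        raise ValueError(f"channel mismatch: input {x.shape[1]}, weight {cin}")
    cols, oh, ow, padded_hw = _im2col(x.data, kh, kw, stride, pad)
    # (F,C,kh,kw) . (N,C,kh,kw,oh,ow) -> (F,N,oh,ow)
    out = np.tensordot(weight.data, cols, axes=([1, 2, 3], [1, 2, 3]))
    out = out.transpose(1, 0, 2, 3)
    if bias is not None:
        out = out + bias.data.reshape(1, f, 1, 1)

    n, c = x.shape[0], cin
    hp, wp = padded_hw
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        # g: (N,F,oh,ow)
        dw = np.tensordot(g, cols, axes=([0, 2, 3], [0, 4, 5]))  # (F,C,kh,kw)
        # (F,C,kh,kw) . (N,F,oh,ow) over F -> (C,kh,kw,N,oh,ow)
        dcols = np.tensordot(weight.data, g, axes=([0], [1]))
        dcols = dcols.transpose(3, 0, 1, 2, 4, 5)  # (N,C,kh,kw,oh,ow)
        dxp = np.zeros((n, c, hp, wp))
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[
                    :, :, i, j
                ]
        ph, pw = pad
        dx = dxp[:, :, ph : hp - ph, pw : wp - pw] if (ph or pw) else dxp
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor._from_op(out, parents, bw)


# ---------------------------------------------------------------------------
# bilinear upsampling by a fixed factor of 2 (half-pixel convention)
# ---------------------------------------------------------------------------

def _up2_indices(n: int):
    pos = (np.arange(2 * n) + 0.5) / 2.0 - 0.5
    i0 = np.clip(np.floor(pos).astype(np.intp), 0, n - 1)
    i1 = np.clip(i0 + 1, 0, n - 1)
    w = np.clip(pos - np.floor(pos), 0.0, 1.0)
    w = np.where(i0 == i1, 0.0, w)  # clamped edges take the single sample
    return i0, i1, w


def _interp_axis(x: np.ndarray, axis: int):
    n = x.shape[axis]
    i0, i1, w = _up2_indices(n)
    shape = [1] * x.ndim
    shape[axis] = 2 * n
    wv = w.reshape(shape)
    return (
        np.take(x, i0, axis=axis) * (1.0 - wv) + np.take(x, i1, axis=axis) * wv,
        (i0, i1, w),
    )


def _interp_axis_backward(g: np.ndarray, n: int, axis: int, idx):
    i0, i1, w = idx
    shape = [1] * g.ndim
    shape[axis] = 2 * n
    wv = w.reshape(shape)
    out_shape = list(g.shape)
    out_shape[axis] = n
    dx = np.zeros(out_shape)
    gm = np.moveaxis(dx, axis, 0)
    g0 = np.moveaxis(g * (1.0 - wv), axis, 0)
    g1 = np.moveaxis(g * wv, axis, 0)
    np.add.at(gm, i0, g0)
    np.add.at(gm, i1, g1)
    return dx


def upsample2x_bilinear(x: Tensor) -> Tensor:
    """Upsample an NCHW tensor by 2x in H and W with bilinear interpolation."""
    x = Tensor._lift(x)
    if x.ndim != 4:
        raise ValueError(f"upsample2x_bilinear expects NCHW input, got {x.shape}")
    h, w = x.shape[2], x.shape[3]
    yh, idx_h = _interp_axis(x.data, axis=2)
    y, idx_w = _interp_axis(yh, axis=3)

    def bw(g):
        g = _interp_axis_backward(g, w, 3, idx_w)
        g = _interp_axis_backward(g, h, 2, idx_h)
        return (g,)

    return Tensor._from_op(y, (x,), bw)
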