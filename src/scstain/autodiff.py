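"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the translation/registration networks
need: broadcasted arithmetic, matmul, pointwise nonlinearities,
reductions, 2-D padding/convolution/pooling/upsampling, bilinear
warping and spatial gathering.  Arrays are float64 throughout; image
tensors use the NCHW layout.
"""

from __future__ import annotations

import contextlib

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (forward passes only) within the block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


class Tensor:
    """A numpy array plus gradient bookkeeping for reverse-mode AD."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # so ndarray + Tensor defers to Tensor

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self):
        return float(self.data)

    def detach(self):
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float64)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # free graph references so intermediates can be collected
        for t in topo:
            t._backward = None
            t._parents = ()

    # -- operator sugar -------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(other, -1.0) if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / np.asarray(other))

    def __matmul__(self, other):
        return matmul(self, other)

    def __pow__(self, p):
        return power(self, p)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _accumulate(t, g):
    if not (t.requires_grad or t._parents):
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g, dtype=np.float64)
    else:
        t.grad = t.grad + g


def _make(data, parents, backward):
    out = Tensor(data)
    track = _grad_enabled and any(p.requires_grad or p._parents
                                  for p in parents)
    if track:
        out._parents = tuple(parents)
        out._backward = backward
        out.requires_grad = False
    return out


def _unbroadcast(g, shape):
    """Reduce gradient ``g`` back to ``shape`` after numpy broadcasting."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# arithmetic
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, p):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        _accumulate(a, g * p * a.data ** (p - 1))

    return _make(out_data, (a,), backward)


def sqrt0(a):
    """Square root with subgradient 0 at 0 (safe for TV norms)."""
    a = as_tensor(a)
    root = np.sqrt(a.data)

    def backward(g):
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(root > 0, 0.5 / np.where(root > 0, root, 1.0), 0.0)
        _accumulate(a, g * d)

    return _make(root, (a,), backward)


def texp(a):
    a = as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * out_data)

    return _make(out_data, (a,), backward)


def tlog(a):
    a = as_tensor(a)

    def backward(g):
        _accumulate(a, g / a.data)

    return _make(np.log(a.data), (a,), backward)


def tabs(a):
    a = as_tensor(a)

    def backward(g):
        _accumulate(a, g * np.sign(a.data))

    return _make(np.abs(a.data), (a,), backward)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0

    def backward(g):
        _accumulate(a, g * mask)

    return _make(a.data * mask, (a,), backward)


def leaky_relu(a, slope=0.2):
    a = as_tensor(a)
    mask = a.data > 0
    scale = np.where(mask, 1.0, slope)

    def backward(g):
        _accumulate(a, g * scale)

    return _make(a.data * scale, (a,), backward)


def sigmoid(a):
    a = as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def tanh(a):
    a = as_tensor(a)
    t = np.tanh(a.data)

    def backward(g):
        _accumulate(a, g * (1.0 - t * t))

    return _make(t, (a,), backward)


# ---------------------------------------------------------------------------
# reductions / shaping
# ---------------------------------------------------------------------------

def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(a_ % a.data.ndim for a_ in axes):
                g = np.expand_dims(g, ax)
        _accumulate(a, np.broadcast_to(g, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis, keepdims), 1.0 / float(n))


def reshape(a, shape):
    a = as_tensor(a)
    orig = a.data.shape

    def backward(g):
        _accumulate(a, g.reshape(orig))

    return _make(a.data.reshape(shape), (a,), backward)


def transpose(a, axes):
    a = as_tensor(a)
    inv = np.argsort(axes)

    def backward(g):
        _accumulate(a, g.transpose(inv))

    return _make(a.data.transpose(axes), (a,), backward)


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return _make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(a.data @ b.data, (a, b), backward)


# ---------------------------------------------------------------------------
# 2-D image ops (NCHW)
# ---------------------------------------------------------------------------

def _unpad_axis_reflect(g, p, axis):
    """Backward of np.pad(..., mode='reflect') along one axis."""
    n = g.shape[axis]
    core = np.take(g, np.arange(p, n - p), axis=axis).copy()
    if p > 0:
        left = np.flip(np.take(g, np.arange(0, p), axis=axis), axis=axis)
        right = np.flip(np.take(g, np.arange(n - p, n), axis=axis), axis=axis)
        idx = [slice(None)] * g.ndim
        idx[axis] = slice(1, p + 1)
        core[tuple(idx)] += left
        idx[axis] = slice(core.shape[axis] - p - 1, core.shape[axis] - 1)
        core[tuple(idx)] += right
    return core


def pad2d(a, p, mode="reflect", value=0.0):
    """Pad the two trailing axes by ``p`` on each side."""
    a = as_tensor(a)
    if p == 0:
        return a
    width = [(0, 0)] * (a.data.ndim - 2) + [(p, p), (p, p)]
    if mode == "reflect":
        data = np.pad(a.data, width, mode="reflect")
    else:
        data = np.pad(a.data, width, mode="constant", constant_values=value)

    def backward(g):
        if mode == "reflect":
            g = _unpad_axis_reflect(g, p, g.ndim - 1)
            g = _unpad_axis_reflect(g, p, g.ndim - 2)
        else:
            sl = [slice(None)] * (g.ndim - 2) + [slice(p, -p), slice(p, -p)]
            g = g[tuple(sl)]
        _accumulate(a, g)

    return _make(data, (a,), backward)


def conv2d(x, w, b=None):
    """Valid (no-padding) stride-1 correlation; x (N,C,H,W), w (O,C,kh,kw)."""
    x, w = as_tensor(x), as_tensor(w)
    kh, kw = w.data.shape[2], w.data.shape[3]
    win = sliding_window_view(x.data, (kh, kw), axis=(2, 3))
    out_data = np.einsum("nchwuv,ocuv->nohw", win, w.data, optimize=True)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[None, :, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        _accumulate(w, np.einsum("nchwuv,nohw->ocuv", win, g, optimize=True))
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        gp = np.pad(g, ((0, 0), (0, 0), (kh - 1, kh - 1), (kw - 1, kw - 1)))
        gwin = sliding_window_view(gp, (kh, kw), axis=(2, 3))
        wf = w.data[:, :, ::-1, ::-1]
        _accumulate(x, np.einsum("nohwuv,ocuv->nchw", gwin, wf, optimize=True))

    return _make(out_data, parents, backward)


def avg_pool2d(x):
    """2x2 average pooling; spatial dims must be even."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError("avg_pool2d requires even spatial dimensions")
    out_data = x.data.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        _accumulate(x, gx)

    return _make(out_data, (x,), backward)


def upsample_nearest(x, s):
    x = as_tensor(x)
    out_data = np.repeat(np.repeat(x.data, s, axis=2), s, axis=3)

    def backward(g):
        n, c, h, w = x.data.shape
        _accumulate(x, g.reshape(n, c, h, s, w, s).sum(axis=(3, 5)))

    return _make(out_data, (x,), backward)


def upsample_zero(x, s):
    """Zero-stuffing upsample: values land on the (i*s, j*s) grid."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, h * s, w * s))
    out_data[:, :, ::s, ::s] = x.data

    def backward(g):
        _accumulate(x, g[:, :, ::s, ::s])

    return _make(out_data, (x,), backward)


def _bilinear_gather(img, rows, cols):
    """Sample img (...,H,W) at float coords with border clamping.

    Returns sampled values plus everything the backward pass needs.
    """
    h, w = img.shape[-2], img.shape[-1]
    r = np.clip(rows, 0.0, h - 1.0)
    c = np.clip(cols, 0.0, w - 1.0)
    r0 = np.floor(r).astype(np.intp)
    c0 = np.floor(c).astype(np.intp)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = r - r0
    fc = c - c0
    v00 = img[..., r0, c0]
    v01 = img[..., r0, c1]
    v10 = img[..., r1, c0]
    v11 = img[..., r1, c1]
    top = v00 * (1 - fc) + v01 * fc
    bot = v10 * (1 - fc) + v11 * fc
    out = top * (1 - fr) + bot * fr
    aux = (r0, c0, r1, c1, fr, fc, v00, v01, v10, v11, rows, cols, h, w)
    return out, aux


def warp(img, phi):
    """Backward warp: out(p) = img(p + phi(p)), bilinear, border clamp.

    img: Tensor (N,C,H,W); phi: Tensor (N,2,H,W) with (d_row, d_col).
    Differentiable with respect to both inputs.
    """
    img, phi = as_tensor(img), as_tensor(phi)
    n, c, h, w = img.data.shape
    gr, gc = np.meshgrid(np.arange(h, dtype=np.float64),
                         np.arange(w, dtype=np.float64), indexing="ij")
    rows = gr[None] + phi.data[:, 0]
    cols = gc[None] + phi.data[:, 1]
    outs = np.empty_like(img.data)
    auxes = []
    for i in range(n):
        out_i, aux = _bilinear_gather(img.data[i], rows[i], cols[i])
        outs[i] = out_i
        auxes.append(aux)

    def backward(g):
        gimg = np.zeros_like(img.data) if (img.requires_grad or img._parents) else None
        gphi = np.zeros_like(phi.data) if (phi.requires_grad or phi._parents) else None
        for i in range(n):
            r0, c0, r1, c1, fr, fc, v00, v01, v10, v11, rw, cl, hh, ww = auxes[i]
            gi = g[i]
            if gimg is not None:
                np.add.at(gimg[i], (slice(None), r0, c0), gi * (1 - fr) * (1 - fc))
                np.add.at(gimg[i], (slice(None), r0, c1), gi * (1 - fr) * fc)
                np.add.at(gimg[i], (slice(None), r1, c0), gi * fr * (1 - fc))
                np.add.at(gimg[i], (slice(None), r1, c1), gi * fr * fc)
            if gphi is not None:
                # d out / d row = bottom - top ; d out / d col analogous
                d_dr = (v10 * (1 - fc) + v11 * fc) - (v00 * (1 - fc) + v01 * fc)
                d_dc = (v01 * (1 - fr) + v11 * fr) - (v00 * (1 - fr) + v10 * fr)
                inside_r = (rw >= 0) & (rw <= hh - 1)
                inside_c = (cl >= 0) & (cl <= ww - 1)
                gphi[i, 0] = (gi * d_dr).sum(axis=0) * inside_r
                gphi[i, 1] = (gi * d_dc).sum(axis=0) * inside_c
        if gimg is not None:
            _accumulate(img, gimg)
        if gphi is not None:
            _accumulate(phi, gphi)

    return _make(outs, (img, phi), backward)


def crop2d(a, h, w):
    """Keep the top-left (h, w) spatial window of an NCHW tensor."""
    a = as_tensor(a)
    H, W = a.data.shape[2], a.data.shape[3]

    def backward(g):
        gx = np.zeros_like(a.data)
        gx[:, :, :h, :w] = g
        _accumulate(a, gx)

    return _make(a.data[:, :, :h, :w].copy(), (a,), backward)


def gather_spatial(x, idx):
    """Pick spatial sites idx (flat indices, shape (S,)) from x (N,C,H,W).

    Returns (N, S, C).
    """
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    out_data = flat[:, :, idx].transpose(0, 2, 1)

    def backward(g):
        gx = np.zeros((n, c, h * w))
        np.add.at(gx, (slice(None), slice(None), idx), g.transpose(0, 2, 1))
        _accumulate(x, gx.reshape(n, c, h, w))

    return _make(out_data, (x,), backward)
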