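"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine: every operation records its parents and a
closure that maps the output gradient to parent gradients.  ``backward()``
on a scalar walks the tape in reverse topological order.  Gradients are
accumulated on every node in the graph, so intermediate activations can be
inspected after the backward pass (used for class-activation heatmaps).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _backward=None):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = _backward

    # ------------------------------------------------------------------ misc
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # ------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        grad = np.asarray(grad, dtype=self.data.dtype)

        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs must not hit the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))

        self.grad = grad if self.grad is None else self.grad + grad
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in node._backward(node.grad):
                if not parent.requires_grad:
                    continue
                pgrad = np.asarray(pgrad)
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # ------------------------------------------------------------ operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_ensure(other), -1.0))

    def __rsub__(self, other):
        return add(_ensure(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _ensure(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_ensure(other), power(self, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def _ensure(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _make(data, parents, backward) -> Tensor:
    requires = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=requires,
                  _parents=tuple(parents) if requires else (),
                  _backward=backward if requires else None)


# ---------------------------------------------------------------- elementwise
def add(a, b):
    a, b = _ensure(a), _ensure(b)
    out = a.data + b.data

    def bwd(g):
        return ((a, _unbroadcast(g, a.data.shape)), (b, _unbroadcast(g, b.data.shape)))

    return _make(out, (a, b), bwd)


def mul(a, b):
    a, b = _ensure(a), _ensure(b)
    out = a.data * b.data

    def bwd(g):
        return ((a, _unbroadcast(g * b.data, a.data.shape)),
                (b, _unbroadcast(g * a.data, b.data.shape)))

    return _make(out, (a, b), bwd)


def power(a, exponent: float):
    a = _ensure(a)
    out = a.data ** exponent

    def bwd(g):
        return ((a, g * exponent * a.data ** (exponent - 1.0)),)

    return _make(out, (a,), bwd)


def exp(a):
    a = _ensure(a)
    out = np.exp(a.data)

    def bwd(g):
        return ((a, g * out),)

    return _make(out, (a,), bwd)


def log(a):
    a = _ensure(a)
    out = np.log(a.data)

    def bwd(g):
        return ((a, g / a.data),)

    return _make(out, (a,), bwd)


def relu(a):
    a = _ensure(a)
    mask = a.data > 0
    out = a.data * mask

    def bwd(g):
        return ((a, g * mask),)

    return _make(out, (a,), bwd)


def sigmoid(a):
    a = _ensure(a)
    from scipy.special import expit  # overflow-free logistic
    out = expit(a.data)

    def bwd(g):
        return ((a, g * out * (1.0 - out)),)

    return _make(out, (a,), bwd)


def clamp(a, lo: float, hi: float):
    """Clip values; gradient passes through only inside the interval."""
    a = _ensure(a)
    out = np.clip(a.data, lo, hi)
    mask = (a.data > lo) & (a.data < hi)

    def bwd(g):
        return ((a, g * mask),)

    return _make(out, (a,), bwd)


# ------------------------------------------------------------------ reshaping
def reshape(a, shape):
    a = _ensure(a)
    out = a.data.reshape(shape)
    orig = a.data.shape

    def bwd(g):
        return ((a, g.reshape(orig)),)

    return _make(out, (a,), bwd)


def transpose(a, axes):
    a = _ensure(a)
    axes = tuple(axes)
    out = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def bwd(g):
        return ((a, g.transpose(inv)),)

    return _make(out, (a,), bwd)


def getitem(a, idx):
    a = _ensure(a)
    out = a.data[idx]

    def bwd(g):
        full = np.zeros_like(a.data)
        np.add.at(full, idx, g)
        return ((a, full),)

    return _make(out, (a,), bwd)


def concat(tensors, axis: int = 0):
    tensors = [_ensure(t) for t in tensors]
    out = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        pairs = []
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            pairs.append((t, g[tuple(sl)]))
        return tuple(pairs)

    return _make(out, tuple(tensors), bwd)


# ----------------------------------------------------------------- reductions
def tsum(a, axis=None, keepdims=False):
    a = _ensure(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if axis is None:
            return ((a, np.broadcast_to(g, a.data.shape).copy()),)
        g2 = g
        if not keepdims:
            g2 = np.expand_dims(g, axis)
        return ((a, np.broadcast_to(g2, a.data.shape).copy()),)

    return _make(out, (a,), bwd)


def tmean(a, axis=None, keepdims=False):
    a = _ensure(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def softmax(a, axis: int = -1, temperature: float = 1.0):
    """Numerically stabilised softmax (max subtracted as a constant)."""
    a = _ensure(a)
    scaled = mul(a, float(temperature))
    shift = np.max(scaled.data, axis=axis, keepdims=True)
    e = exp(add(scaled, Tensor(-shift)))
    return mul(e, power(tsum(e, axis=axis, keepdims=True), -1.0))


def amax(a, axis: int, keepdims: bool = False):
    """Maximum along one axis; the gradient flows to the (first) argmax."""
    a = _ensure(a)
    arg = a.data.argmax(axis=axis)
    out = np.take_along_axis(a.data, np.expand_dims(arg, axis), axis=axis)
    if not keepdims:
        out = np.squeeze(out, axis=axis)

    def bwd(g):
        g2 = g if keepdims else np.expand_dims(g, axis)
        full = np.zeros_like(a.data)
        np.put_along_axis(full, np.expand_dims(arg, axis), g2, axis=axis)
        return ((a, full),)

    return _make(out, (a,), bwd)


# -------------------------------------------------------------------- linear
def matmul(a, b):
    a, b = _ensure(a), _ensure(b)
    out = a.data @ b.data

    def bwd(g):
        return ((a, g @ b.data.T), (b, a.data.T @ g))

    return _make(out, (a, b), bwd)


# --------------------------------------------------------------- convolution
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, padding: int):
    n, c, h, w = x.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    # (N, C, OH, OW, kh, kw) -> (N*OH*OW, C*kh*kw)
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n * oh * ow, c * kh * kw)
    return np.ascontiguousarray(cols), oh, ow


def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0):
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    x, weight = _ensure(x), _ensure(weight)
    n, c, h, w = x.data.shape
    o, ci, kh, kw = weight.data.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight expects {ci}")
    cols, oh, ow = _im2col(x.data, kh, kw, stride, padding)
    wmat = weight.data.reshape(o, -1)
    out = cols @ wmat.T
    if bias is not None:
        bias = _ensure(bias)
        out = out + bias.data
    out = out.reshape(n, oh, ow, o).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def bwd(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * oh * ow, o)
        pairs = []
        if x.requires_grad:
            dcols = gm @ wmat                      # (N*OH*OW, C*kh*kw)
            dcols = dcols.reshape(n, oh, ow, c, kh, kw)
            hp, wp = h + 2 * padding, w + 2 * padding
            dxp = np.zeros((n, c, hp, wp), dtype=g.dtype)
            for i in range(kh):                    # kh*kw strided adds: col2im
                for j in range(kw):
                    dxp[:, :, i:i + stride * oh:stride,
                        j:j + stride * ow:stride] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            pairs.append((x, dxp))
        if weight.requires_grad:
            pairs.append((weight, (gm.T @ cols).reshape(weight.data.shape)))
        if bias is not None and bias.requires_grad:
            pairs.append((bias, gm.sum(axis=0)))
        return tuple(pairs)

    return _make(out, parents, bwd)


def max_pool2d(x, kernel: int = 3, stride: int = 2, padding: int = 1):
    x = _ensure(x)
    n, c, h, w = x.data.shape
    neg = np.finfo(x.data.dtype).min if np.issubdtype(x.data.dtype, np.floating) else -np.inf
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)),
                constant_values=neg)
    oh = (xp.shape[2] - kernel) // stride + 1
    ow = (xp.shape[3] - kernel) // stride + 1
    view = sliding_window_view(xp, (kernel, kernel), axis=(2, 3))[:, :, ::stride, ::stride]
    flat = view.reshape(n, c, oh, ow, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def bwd(g):
        dxp = np.zeros_like(xp)
        ki, kj = np.divmod(arg, kernel)
        ii = (np.arange(oh)[None, None, :, None] * stride + ki)
        jj = (np.arange(ow)[None, None, None, :] * stride + kj)
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding:-padding, padding:-padding]
        return ((x, dxp),)

    return _make(out, (x,), bwd)


# ------------------------------------------------------- bilinear upsampling
def _bilinear_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """Row-stochastic interpolation matrix, half-pixel (align_corners=false)."""
    scale = n_in / n_out
    src = (np.arange(n_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    mat = np.zeros((n_out, n_in), dtype=dtype)
    mat[np.arange(n_out), lo] += 1.0 - frac
    mat[np.arange(n_out), hi] += frac
    return mat


def upsample_bilinear(x, out_h: int, out_w: int):
    x = _ensure(x)
    n, c, h, w = x.data.shape
    ah = _bilinear_matrix(h, out_h, x.data.dtype)
    aw = _bilinear_matrix(w, out_w, x.data.dtype)
    out = np.einsum("ph,nchw,qw->ncpq", ah, x.data, aw, optimize=True)

    def bwd(g):
        return ((x, np.einsum("ph,ncpq,qw->nchw", ah, g, aw, optimize=True)),)

    return _make(out, (x,), bwd)
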