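"""Minimal reverse-mode automatic differentiation on numpy arrays.

The package trains small convolutional networks on the CPU, so this module
implements exactly the operations the architecture needs — elementwise
arithmetic, matmul, 3x3/1x1 convolutions (stride 1, "same" padding, with
2x2 max-pooling for downsampling), nearest-neighbour x2 upsampling, group
normalization, softmax, channel dropout and the usual reductions — each with
an analytic backward pass.  All tensors are float32, images are NCHW.

Convolution is im2col + BLAS matmul; its data gradient is itself a "same"
convolution with the spatially flipped, channel-transposed kernel, so no
scatter (col2im) is ever needed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "relu", "sigmoid", "log", "exp", "absolute",
    "clip", "power", "matmul", "softmax", "concat", "reshape", "tsum",
    "tmean", "tmax", "conv2d", "maxpool2", "upsample2", "groupnorm",
    "global_maxpool", "channel_dropout", "gather_channel",
]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    # make numpy defer to Tensor.__r*__ in mixed ndarray-Tensor expressions
    __array_ufunc__ = None
    __array_priority__ = 1000

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    # ------------------------------------------------------------------ basic
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -------------------------------------------------------------- operators
    def __add__(self, other):
        return _add(self, as_tensor(other))

    __radd__ = __add__

    def __mul__(self, other):
        return _mul(self, as_tensor(other))

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return _mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, as_tensor(other))

    # -------------------------------------------------------------- backward
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
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
                if id(p) not in seen and (p.requires_grad or p._parents):
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node is not self and node._parents:
                # free intermediate grads/graph to bound memory
                node.grad = None if not node.requires_grad else node.grad


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


_GRAD_ENABLED = [True]


class no_grad:
    """Context manager disabling graph construction (inference mode)."""

    def __enter__(self):
        self._prev = _GRAD_ENABLED[0]
        _GRAD_ENABLED[0] = False

    def __exit__(self, *exc):
        _GRAD_ENABLED[0] = self._prev
        return False


def grad_enabled() -> bool:
    return _GRAD_ENABLED[0]


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED[0] and any(p.requires_grad or p._parents
                                for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _accum(t: Tensor, g) -> None:
    if t.requires_grad or t._parents:
        t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g, shape):
    """Sum gradient g down to `shape` (inverse of numpy broadcasting)."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g.astype(np.float32)


# ------------------------------------------------------------------- elementwise
def _add(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), bwd)


def _mul(a: Tensor, b: Tensor) -> Tensor:
    def bwd(g):
        _accum(a, _unbroadcast(g * b.data, a.data.shape))
        _accum(b, _unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), bwd)


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0

    def bwd(g):
        _accum(x, g * mask)
    return _make(np.where(mask, x.data, 0.0), (x,), bwd)


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = 1.0 / (1.0 + np.exp(-x.data))

    def bwd(g):
        _accum(x, g * y * (1.0 - y))
    return _make(y, (x,), bwd)


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)

    def bwd(g):
        _accum(x, g / x.data)
    return _make(np.log(x.data), (x,), bwd)


def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    y = np.exp(x.data)

    def bwd(g):
        _accum(x, g * y)
    return _make(y, (x,), bwd)


def absolute(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = np.sign(x.data)

    def bwd(g):
        _accum(x, g * s)
    return _make(np.abs(x.data), (x,), bwd)


def clip(x: Tensor, lo: float, hi: float) -> Tensor:
    """Hard clip; gradient is zero outside [lo, hi]."""
    x = as_tensor(x)
    mask = (x.data >= lo) & (x.data <= hi)

    def bwd(g):
        _accum(x, g * mask)
    return _make(np.clip(x.data, lo, hi), (x,), bwd)


def power(x: Tensor, p: float) -> Tensor:
    x = as_tensor(x)
    y = x.data ** p

    def bwd(g):
        _accum(x, g * p * x.data ** (p - 1.0))
    return _make(y, (x,), bwd)


# ------------------------------------------------------------------- linear alg
def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)

    def bwd(g):
        _accum(a, g @ b.data.T)
        _accum(b, a.data.T @ g)
    return _make(a.data @ b.data, (a, b), bwd)


# ------------------------------------------------------------------- reductions
def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    shape = x.data.shape

    def bwd(g):
        if axis is None:
            gg = np.broadcast_to(g, shape)
        else:
            gexp = g if keepdims else np.expand_dims(g, axis)
            gg = np.broadcast_to(gexp, shape)
        _accum(x, gg.astype(np.float32))
    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), bwd)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    n = x.data.size if axis is None else np.prod(
        [x.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
    return tsum(x, axis=axis, keepdims=keepdims) * (1.0 / float(n))


def tmax(x: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    x = as_tensor(x)
    idx = np.argmax(x.data, axis=axis)
    y = np.take_along_axis(x.data, np.expand_dims(idx, axis), axis)

    def bwd(g):
        gexp = g if keepdims else np.expand_dims(g, axis)
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, np.expand_dims(idx, axis), gexp, axis)
        _accum(x, gx)
    out = y if keepdims else y.squeeze(axis)
    return _make(out, (x,), bwd)


# ------------------------------------------------------------------- structure
def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    bounds = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, bounds[:-1], bounds[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bwd)


def reshape(x: Tensor, shape) -> Tensor:
    x = as_tensor(x)
    old = x.data.shape

    def bwd(g):
        _accum(x, g.reshape(old))
    return _make(x.data.reshape(shape), (x,), bwd)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        _accum(x, y * (g - dot))
    return _make(y, (x,), bwd)


def take_rows(x: Tensor, idx) -> Tensor:
    """Select (with possible repetition) rows along axis 0."""
    x = as_tensor(x)
    idx = np.asarray(idx, dtype=np.int64)

    def bwd(g):
        gx = np.zeros_like(x.data)
        for r in np.unique(idx):  # few distinct rows; avoids slow add.at
            gx[r] = g[idx == r].sum(axis=0)
        _accum(x, gx)
    return _make(x.data[idx], (x,), bwd)


def gather_channel(x: Tensor, idx: np.ndarray) -> Tensor:
    """y[n, h, w] = x[n, idx[n, h, w], h, w] for NCHW x and integer idx."""
    x = as_tensor(x)
    idx4 = idx[:, None].astype(np.int64)
    y = np.take_along_axis(x.data, idx4, axis=1)[:, 0]

    def bwd(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx4, g[:, None], axis=1)
        _accum(x, gx)
    return _make(y, (x,), bwd)


# ------------------------------------------------------------------- conv & co.
def _shift_cols(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(kh*kw*Cin, N*H*W) patch matrix built from contiguous strip copies.

    Far cheaper than a sliding-window gather: each of the kh*kw source
    slices copies long contiguous rows.
    """
    n, cin, h, wid = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    xt = xp.transpose(1, 0, 2, 3)  # (Cin, N, Hp, Wp) view
    buf = np.empty((kh * kw * cin, n * h * wid), np.float32)
    k = 0
    for di in range(kh):
        for dj in range(kw):
            np.copyto(buf[k * cin:(k + 1) * cin].reshape(cin, n, h, wid),
                      xt[:, :, di:di + h, dj:dj + wid])
            k += 1
    return buf


def _conv2d_same_raw(x: np.ndarray, w: np.ndarray,
                     cols: np.ndarray | None = None) -> np.ndarray:
    """Plain stride-1 'same' convolution of NCHW x with (Cout,Cin,kh,kw) w."""
    n, cin, h, wid = x.shape
    cout, _, kh, kw = w.shape
    if kh == kw == 1:
        y = w.reshape(cout, cin) @ x.transpose(1, 0, 2, 3).reshape(cin, -1)
    else:
        wmat = w.transpose(0, 2, 3, 1).reshape(cout, kh * kw * cin)
        y = wmat @ (_shift_cols(x, kh, kw) if cols is None else cols)
    return np.ascontiguousarray(
        y.reshape(cout, n, h, wid).transpose(1, 0, 2, 3))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Stride-1 'same' 2-D convolution (odd kernels only).

    The patch matrix built for the forward GEMM is kept for the weight
    gradient (training batches are small, so the memory is cheap compared
    with rebuilding it).
    """
    x, w = as_tensor(x), as_tensor(w)
    cout, cin, kh, kw = w.data.shape
    needs_grad = _GRAD_ENABLED[0] and \
        any(p.requires_grad or p._parents for p in (x, w))
    cached = _shift_cols(x.data, kh, kw) \
        if needs_grad and not kh == kw == 1 else None
    y = _conv2d_same_raw(x.data, w.data, cached)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data[None, :, None, None]
    parents = (x, w) if b is None else (x, w, b)

    def bwd(g):
        n, _, h, wid = x.data.shape
        g2 = np.ascontiguousarray(
            g.transpose(1, 0, 2, 3)).reshape(cout, n * h * wid)
        if kh == kw == 1:
            xf = x.data.transpose(1, 0, 2, 3).reshape(cin, -1)
            _accum(w, (g2 @ xf.T).reshape(cout, cin, 1, 1))
            dx = w.data.reshape(cout, cin).T @ g2
            _accum(x, np.ascontiguousarray(
                dx.reshape(cin, n, h, wid).transpose(1, 0, 2, 3)))
        else:
            cols = cached
            gw = g2 @ cols.T  # (Cout, kh*kw*Cin)
            _accum(w, gw.reshape(cout, kh, kw, cin).transpose(0, 3, 1, 2))
            if x.requires_grad or x._parents:  # skip dX at the input layer
                wmat = w.data.transpose(0, 2, 3, 1).reshape(
                    cout, kh * kw * cin)
                big = wmat.T @ g2  # (kh*kw*Cin, NHW)
                ph, pw = kh // 2, kw // 2
                dxp = np.zeros((cin, n, h + 2 * ph, wid + 2 * pw),
                               np.float32)
                k = 0
                for di in range(kh):
                    for dj in range(kw):
                        dxp[:, :, di:di + h, dj:dj + wid] += \
                            big[k * cin:(k + 1) * cin].reshape(cin, n, h, wid)
                        k += 1
                _accum(x, np.ascontiguousarray(
                    dxp[:, :, ph:ph + h, pw:pw + wid].transpose(1, 0, 2, 3)))
        if b is not None:
            _accum(b, g.sum(axis=(0, 2, 3)))
    return _make(y, parents, bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; H and W must be even."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    xr = (x.data.reshape(n, c, h // 2, 2, w // 2, 2)
          .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4))
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        g4 = np.zeros_like(xr)
        np.put_along_axis(g4, idx[..., None], g[..., None], axis=-1)
        gx = (g4.reshape(n, c, h // 2, w // 2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w))
        _accum(x, gx)
    return _make(y, (x,), bwd)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour x2 upsampling."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape

    def bwd(g):
        _accum(x, g.reshape(n, c, h, 2, w, 2).sum(axis=(3, 5)))
    return _make(x.data.repeat(2, axis=2).repeat(2, axis=3), (x,), bwd)


def pad2d_to_even(x: Tensor) -> Tensor:
    """Zero-pad bottom/right so H and W are even (no-op when already even)."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    ph, pw = h % 2, w % 2
    if not (ph or pw):
        return x

    def bwd(g):
        _accum(x, g[:, :, :h, :w])
    return _make(np.pad(x.data, ((0, 0), (0, 0), (0, ph), (0, pw))), (x,), bwd)


def global_maxpool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) max over the spatial dimensions."""
    x = as_tensor(x)
    n, c, h, w = x.data.shape
    flat = x.data.reshape(n, c, h * w)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gx = np.zeros_like(flat)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        _accum(x, gx.reshape(n, c, h, w))
    return _make(y, (x,), bwd)


def groupnorm(x: Tensor, gamma: Tensor, beta: Tensor, groups: int,
              eps: float = 1e-5) -> Tensor:
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    n, c, h, w = x.data.shape
    g_ = groups
    xg = x.data.reshape(n, g_, -1)
    mu = xg.mean(axis=-1, keepdims=True)
    var = xg.var(axis=-1, keepdims=True)
    std = np.sqrt(var + eps)
    xhat = ((xg - mu) / std).reshape(n, c, h, w)
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(gr):
        _accum(gamma, (gr * xhat).sum(axis=(0, 2, 3)))
        _accum(beta, gr.sum(axis=(0, 2, 3)))
        dxhat = (gr * gamma.data[None, :, None, None]).reshape(n, g_, -1)
        xh = xhat.reshape(n, g_, -1)
        m1 = dxhat.mean(axis=-1, keepdims=True)
        m2 = (dxhat * xh).mean(axis=-1, keepdims=True)
        dx = (dxhat - m1 - xh * m2) / std
        _accum(x, dx.reshape(n, c, h, w).astype(np.float32))
    return _make(y, (x, gamma, beta), bwd)


def channel_dropout(x: Tensor, p: float, rng: np.random.Generator) -> Tensor:
    """Zero whole channels with probability p and rescale (training only)."""
    x = as_tensor(x)
    if p <= 0.0:
        return x
    n, c = x.data.shape[:2]
    keep = (rng.random((n, c)) >= p).astype(np.float32) / (1.0 - p)
    mask = keep[:, :, None, None]

    def bwd(g):
        _accum(x, g * mask)
    return _make(x.data * mask, (x,), bwd)
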