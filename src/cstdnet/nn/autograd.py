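"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small define-by-run engine sized for desk-scale detection
experiments: a :class:`Tensor` wraps an ``ndarray``, records the ops applied
to it, and :meth:`Tensor.backward` walks the tape in reverse topological
order.  Only the operations the detection network needs are provided
(elementwise arithmetic, reductions, indexing, 2-D convolution, pooling,
bilinear resampling, batch normalization and a handful of nonlinearities).

All gradients are accumulated into ``Tensor.grad`` as plain numpy arrays.
Broadcasting follows numpy semantics; gradients of broadcast operands are
summed back to the operand's shape.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable tape recording inside the context (inference / bookkeeping)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents = ()
        self._backward = None

    # ---- bookkeeping -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def backward(self):
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
            if node._backward is not None:
                node._backward(node.grad)

    # ---- operator sugar --------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -_as_tensor(other))

    def __rsub__(self, other):
        return add(_as_tensor(other), -self)

    def __truediv__(self, other):
        return div(self, other)

    def __rtruediv__(self, other):
        return div(_as_tensor(other), self)

    def __pow__(self, expo):
        return power(self, expo)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 or isinstance(shape[0], int) else shape[0])

    def transpose(self, *axes):
        return transpose(self, axes)

    def abs(self):
        return tabs(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def _acc(t: Tensor, g: np.ndarray):
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(t.data.dtype, copy=True) if g.dtype != t.data.dtype else g.copy()
    else:
        t.grad += g


def _make(data: np.ndarray, parents: tuple, backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


# ---- elementwise arithmetic ---------------------------------------------

def add(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        _acc(a, _unbroadcast(g, a.data.shape))
        _acc(b, _unbroadcast(g, b.data.shape))

    return _make(out_data, (a, b), backward)


def mul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        _acc(a, _unbroadcast(g * b.data, a.data.shape))
        _acc(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(out_data, (a, b), backward)


def div(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def backward(g):
        _acc(a, _unbroadcast(g / b.data, a.data.shape))
        _acc(b, _unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

    return _make(out_data, (a, b), backward)


def power(a, expo: float):
    a = _as_tensor(a)
    out_data = a.data ** expo

    def backward(g):
        _acc(a, g * expo * a.data ** (expo - 1))

    return _make(out_data, (a,), backward)


def texp(a):
    a = _as_tensor(a)
    out_data = np.exp(a.data)

    def backward(g):
        _acc(a, g * out_data)

    return _make(out_data, (a,), backward)


def tlog(a):
    a = _as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        _acc(a, g / a.data)

    return _make(out_data, (a,), backward)


def tsqrt(a):
    a = _as_tensor(a)
    out_data = np.sqrt(a.data)

    def backward(g):
        _acc(a, g * 0.5 / out_data)

    return _make(out_data, (a,), backward)


def arctan(a):
    a = _as_tensor(a)
    out_data = np.arctan(a.data)

    def backward(g):
        _acc(a, g / (1.0 + a.data * a.data))

    return _make(out_data, (a,), backward)


def tabs(a):
    a = _as_tensor(a)
    out_data = np.abs(a.data)

    def backward(g):
        _acc(a, g * np.sign(a.data))

    return _make(out_data, (a,), backward)


def sigmoid(a):
    a = _as_tensor(a)
    out_data = _expit(a.data)

    def backward(g):
        _acc(a, g * out_data * (1.0 - out_data))

    return _make(out_data, (a,), backward)


def silu(a):
    """x * sigmoid(x), the YOLO-family default activation."""
    a = _as_tensor(a)
    s = _expit(a.data)
    out_data = a.data * s

    def backward(g):
        _acc(a, g * s * (1.0 + a.data * (1.0 - s)))

    return _make(out_data, (a,), backward)


def _expit(x) -> np.ndarray:
    xa = np.atleast_1d(np.asarray(x))
    out = np.empty(xa.shape, dtype=np.result_type(xa, np.float32))
    pos = xa >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-xa[pos]))
    ex = np.exp(xa[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out.reshape(np.shape(x))


def softplus(a):
    a = _as_tensor(a)
    x = a.data
    out_data = np.maximum(x, 0) + np.log1p(np.exp(-np.abs(x)))

    def backward(g):
        _acc(a, g * _expit(x))

    return _make(out_data, (a,), backward)


def maximum(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.maximum(a.data, b.data)
    mask = a.data >= b.data  # ties routed to the first operand

    def backward(g):
        _acc(a, _unbroadcast(g * mask, a.data.shape))
        _acc(b, _unbroadcast(g * ~mask, b.data.shape))

    return _make(out_data, (a, b), backward)


def minimum(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = np.minimum(a.data, b.data)
    mask = a.data <= b.data

    def backward(g):
        _acc(a, _unbroadcast(g * mask, a.data.shape))
        _acc(b, _unbroadcast(g * ~mask, b.data.shape))

    return _make(out_data, (a, b), backward)


def clip(a, lo=None, hi=None):
    a = _as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        mask &= a.data >= lo
    if hi is not None:
        mask &= a.data <= hi

    def backward(g):
        _acc(a, g * mask)

    return _make(out_data, (a,), backward)


# ---- shape ops -----------------------------------------------------------

def reshape(a, shape):
    a = _as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        _acc(a, g.reshape(a.data.shape))

    return _make(out_data, (a,), backward)


def transpose(a, axes):
    a = _as_tensor(a)
    axes = tuple(axes)
    out_data = a.data.transpose(axes)
    inv = np.argsort(axes)

    def backward(g):
        _acc(a, g.transpose(inv))

    return _make(out_data, (a,), backward)


def getitem(a, idx):
    a = _as_tensor(a)
    out_data = a.data[idx]

    def backward(g):
        ga = np.zeros_like(a.data)
        np.add.at(ga, idx, g)
        _acc(a, ga)

    return _make(out_data, (a,), backward)


def concatenate(tensors, axis=0):
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, gpart in zip(tensors, np.split(g, splits, axis=axis)):
            _acc(t, gpart)

    return _make(out_data, tuple(tensors), backward)


def tsum(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            _acc(a, np.broadcast_to(g, a.data.shape).copy())
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(g, axis)
        _acc(a, np.broadcast_to(gg, a.data.shape).copy())

    return _make(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = _as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / float(n))


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    if a.data.ndim != 2 or b.data.ndim != 2:
        raise ValueError("matmul supports 2-D operands only")
    out_data = a.data @ b.data

    def backward(g):
        _acc(a, g @ b.data.T)
        _acc(b, a.data.T @ g)

    return _make(out_data, (a, b), backward)


# ---- spatial ops ---------------------------------------------------------

def _pair(v):
    return (v, v) if isinstance(v, int) else tuple(v)


def conv2d(x, w, b=None, stride=1, padding=0, dilation=1):
    """2-D cross-correlation, NCHW layout, via kernel-position slicing.

    ``w`` has shape (out_ch, in_ch, kh, kw).  Padding is zero-padding applied
    symmetrically per spatial axis.
    """
    x, w = _as_tensor(x), _as_tensor(w)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    dh, dw = _pair(dilation)
    xd, wd = x.data, w.data
    N, C, H, W = xd.shape
    O, Cw, kh, kw = wd.shape
    if Cw != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Cw}")
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw))) if (ph or pw) else xd
    OH = (H + 2 * ph - dh * (kh - 1) - 1) // sh + 1
    OW = (W + 2 * pw - dw * (kw - 1) - 1) // sw + 1
    cols = np.empty((N, C, kh, kw, OH, OW), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i, j] = xp[
                :, :, i * dh : i * dh + (OH - 1) * sh + 1 : sh,
                j * dw : j * dw + (OW - 1) * sw + 1 : sw,
            ]
    out_data = np.tensordot(wd, cols, axes=((1, 2, 3), (1, 2, 3))).transpose(1, 0, 2, 3)
    parents = (x, w)
    if b is not None:
        out_data = out_data + b.data.reshape(1, -1, 1, 1)
        parents = (x, w, b)

    def backward(g):
        if b is not None and b.requires_grad:
            _acc(b, g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            gw = np.tensordot(g, cols, axes=((0, 2, 3), (0, 4, 5)))
            _acc(w, gw)
        if x.requires_grad:
            gcols = np.tensordot(g, wd, axes=((1,), (0,)))  # N,OH,OW,C,kh,kw
            gcols = gcols.transpose(0, 3, 4, 5, 1, 2)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[
                        :, :, i * dh : i * dh + (OH - 1) * sh + 1 : sh,
                        j * dw : j * dw + (OW - 1) * sw + 1 : sw,
                    ] += gcols[:, :, i, j]
            _acc(x, gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp)

    return _make(out_data, parents, backward)


def max_pool2d(x, kernel, stride=1, padding=0):
    x = _as_tensor(x)
    kh, kw = _pair(kernel)
    sh, sw = _pair(stride)
    ph, pw = _pair(padding)
    xd = x.data
    N, C, H, W = xd.shape
    xp = np.pad(xd, ((0, 0), (0, 0), (ph, ph), (pw, pw)), constant_values=-np.inf) if (ph or pw) else xd
    OH = (H + 2 * ph - kh) // sh + 1
    OW = (W + 2 * pw - kw) // sw + 1
    wins = np.empty((N, C, kh * kw, OH, OW), dtype=xd.dtype)
    for i in range(kh):
        for j in range(kw):
            wins[:, :, i * kw + j] = xp[
                :, :, i : i + (OH - 1) * sh + 1 : sh, j : j + (OW - 1) * sw + 1 : sw
            ]
    arg = wins.argmax(axis=2)
    out_data = np.take_along_axis(wins, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if not x.requires_grad:
            return
        gxp = np.zeros_like(xp, dtype=g.dtype)
        n_i, c_i, oh_i, ow_i = np.indices(arg.shape)
        hi = (arg // kw) + oh_i * sh
        wj = (arg % kw) + ow_i * sw
        np.add.at(gxp, (n_i, c_i, hi, wj), g)
        _acc(x, gxp[:, :, ph : ph + H, pw : pw + W] if (ph or pw) else gxp)

    return _make(out_data, (x,), backward)


def avg_pool2d(x):
    """2x2 average pooling, stride 2; spatial dims must be even."""
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    if H % 2 or W % 2:
        raise ValueError("avg_pool2d requires even spatial dimensions")
    out_data = x.data.reshape(N, C, H // 2, 2, W // 2, 2).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        _acc(x, gx)

    return _make(out_data, (x,), backward)


_BILINEAR_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _bilinear_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Interpolation matrix for 1-D bilinear resampling (align_corners=False)."""
    key = (n_in, n_out)
    mat = _BILINEAR_CACHE.get(key)
    if mat is None:
        mat = np.zeros((n_out, n_in))
        scale = n_in / n_out
        for i in range(n_out):
            src = (i + 0.5) * scale - 0.5
            i0 = int(np.floor(src))
            f = src - i0
            i0c = min(max(i0, 0), n_in - 1)
            i1c = min(max(i0 + 1, 0), n_in - 1)
            mat[i, i0c] += 1.0 - f
            mat[i, i1c] += f
        _BILINEAR_CACHE[key] = mat
    return mat


def upsample_bilinear2x(x):
    x = _as_tensor(x)
    N, C, H, W = x.data.shape
    Ah = _bilinear_matrix(H, 2 * H).astype(x.data.dtype)
    Aw = _bilinear_matrix(W, 2 * W).astype(x.data.dtype)
    y = np.einsum("ph,nchw->ncpw", Ah, x.data)
    out_data = np.einsum("qw,ncpw->ncpq", Aw, y)

    def backward(g):
        gy = np.einsum("qw,ncpq->ncpw", Aw, g)
        _acc(x, np.einsum("ph,ncpw->nchw", Ah, gy))

    return _make(out_data, (x,), backward)


def batch_norm2d(x, gamma, beta, running_mean, running_var, training,
                 momentum=0.1, eps=1e-5):
    """Batch normalization over (N, H, W) per channel.

    ``running_mean``/``running_var`` are plain numpy arrays mutated in place
    when ``training`` is true.
    """
    x = _as_tensor(x)
    xd = x.data
    N, C, H, W = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        m = N * H * W
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xc = xd - mu.reshape(1, C, 1, 1)
    xhat = xc * inv.reshape(1, C, 1, 1)
    out_data = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            _acc(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            _acc(beta, g.sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gxhat = g * gamma.data.reshape(1, C, 1, 1)
        if training:
            m = N * H * W
            invr = inv.reshape(1, C, 1, 1)
            sum_gxhat = gxhat.sum(axis=(0, 2, 3), keepdims=True)
            sum_gxhat_xhat = (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = invr / m * (m * gxhat - sum_gxhat - xhat * sum_gxhat_xhat)
        else:
            gx = gxhat * inv.reshape(1, C, 1, 1)
        _acc(x, gx)

    return _make(out_data, (x, gamma, beta), backward)


def bce_with_logits(logits, targets):
    """Elementwise binary cross entropy on logits (numerically stable)."""
    t = _as_tensor(targets)
    return softplus(logits) - mul(logits, t)
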