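"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps a float64 ndarray and records the operations applied
to it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The op set is exactly what the super-resolution
generators, the relativistic discriminator and their losses need: 2-D
convolution (with stride and dilation), batch statistics, pixel shuffle,
nearest/linear resampling, dense layers and elementwise math.  float64 is used
throughout so analytic gradients agree with central finite differences to
tight tolerance.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "concat", "conv2d", "pixel_shuffle",
    "upsample_nearest", "resize_kernel", "resize_linear", "resize_cubic",
]


class Tensor:
    """A node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._parents: tuple = ()
        self._backward = None

    # -- basic introspection -------------------------------------------------
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

    # -- graph machinery -----------------------------------------------------
    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, power(other, -1.0))

    def __matmul__(self, other):
        return matmul(self, other)

    def reshape(self, *shape):
        return reshape(self, shape)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents, backward):
    out = Tensor(data)
    out.requires_grad = any(p.requires_grad for p in parents)
    if out.requires_grad:
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / reduction ops
# ---------------------------------------------------------------------------

def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a, b):
    if isinstance(b, (int, float)):
        a = as_tensor(a)
        out_data = a.data * b

        def backward_s(g):
            if a.requires_grad:
                a._accumulate(g * b)

        return _node(out_data, (a,), backward_s)

    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def power(a, p: float):
    a = as_tensor(a)
    out_data = a.data ** p

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * p * a.data ** (p - 1.0))

    return _node(out_data, (a,), backward)


def sqrt(a):
    return power(a, 0.5)


def tsum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if not a.requires_grad:
            return
        if axis is None:
            a._accumulate(np.broadcast_to(g, a.data.shape).copy())
        else:
            g2 = g if keepdims else np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g2, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / n)


def tabs(a):
    a = as_tensor(a)
    out_data = np.abs(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.sign(a.data))

    return _node(out_data, (a,), backward)


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    mask = a.data >= 0
    out_data = np.where(mask, a.data, slope * a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * np.where(mask, 1.0, slope))

    return _node(out_data, (a,), backward)


def relu(a):
    return leaky_relu(a, 0.0)


def sigmoid(a):
    a = as_tensor(a)
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * out_data * (1.0 - out_data))

    return _node(out_data, (a,), backward)


def log(a):
    a = as_tensor(a)
    out_data = np.log(a.data)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g / a.data)

    return _node(out_data, (a,), backward)


def clamp(a, lo: float, hi: float):
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    mask = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g * mask)

    return _node(out_data, (a,), backward)


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------

def reshape(a, shape):
    a = as_tensor(a)
    out_data = a.data.reshape(shape)

    def backward(g):
        if a.requires_grad:
            a._accumulate(g.reshape(a.data.shape))

    return _node(out_data, (a,), backward)


def concat(tensors, axis: int = 1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t._accumulate(g[tuple(idx)])

    return _node(out_data, tensors, backward)


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accumulate(g @ b.data.T)
        if b.requires_grad:
            b._accumulate(a.data.T @ g)

    return _node(out_data, (a, b), backward)


# ---------------------------------------------------------------------------
# spatial ops (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d(x, w, b=None, stride: int = 1, dilation: int = 1, padding=None):
    """2-D convolution (cross-correlation) over an NCHW batch.

    ``padding`` defaults to "same" for stride 1 (``dilation*(k-1)//2`` per
    side), matching the 3x3 same-size convolutions used throughout the
    generators.
    """
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W = x.shape
    O, Ci, kh, kw = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight expects {Ci}")
    if padding is None:
        ph, pw = dilation * (kh - 1) // 2, dilation * (kw - 1) // 2
    elif isinstance(padding, int):
        ph = pw = padding
    else:
        ph, pw = padding
    ekh, ekw = dilation * (kh - 1) + 1, dilation * (kw - 1) + 1
    Hp, Wp = H + 2 * ph, W + 2 * pw
    if Hp < ekh or Wp < ekw:
        raise ValueError("conv2d: input smaller than effective kernel")
    OH = (Hp - ekh) // stride + 1
    OW = (Wp - ekw) // stride + 1

    xp = np.zeros((N, C, Hp, Wp))
    xp[:, :, ph:ph + H, pw:pw + W] = x.data

    def _tap(i, j):
        hs = slice(i * dilation, i * dilation + (OH - 1) * stride + 1, stride)
        ws = slice(j * dilation, j * dilation + (OW - 1) * stride + 1, stride)
        return hs, ws

    # im2col in (N, OH, OW, C, kh, kw) layout so the matmul needs no copy
    cols = np.empty((N, OH, OW, C, kh, kw))
    for i in range(kh):
        for j in range(kw):
            hs, ws = _tap(i, j)
            cols[:, :, :, :, i, j] = xp[:, :, hs, ws].transpose(0, 2, 3, 1)
    K = C * kh * kw
    cols2d = cols.reshape(N * OH * OW, K)
    wmat = w.data.reshape(O, K)
    out_data = (cols2d @ wmat.T).reshape(N, OH, OW, O).transpose(0, 3, 1, 2)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data.reshape(1, O, 1, 1)
    else:
        out_data = np.ascontiguousarray(out_data)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g):
        g2d = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, O)
        if w.requires_grad:
            w._accumulate((g2d.T @ cols2d).reshape(O, C, kh, kw))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (g2d @ wmat).reshape(N, OH, OW, C, kh, kw)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    hs, ws = _tap(i, j)
                    dxp[:, :, hs, ws] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accumulate(dxp[:, :, ph:ph + H, pw:pw + W])

    return _node(out_data, parents, backward)


def pixel_shuffle(x, scale: int):
    """Rearrange (N, C*s^2, H, W) -> (N, C, H*s, W*s) (sub-pixel convolution)."""
    x = as_tensor(x)
    N, C, H, W = x.shape
    if C % (scale * scale) != 0:
        raise ValueError("pixel_shuffle: channels not divisible by scale^2")
    Co = C // (scale * scale)
    out_data = (
        x.data.reshape(N, Co, scale, scale, H, W)
        .transpose(0, 1, 4, 2, 5, 3)
        .reshape(N, Co, H * scale, W * scale)
    )

    def backward(g):
        if x.requires_grad:
            gr = (
                g.reshape(N, Co, H, scale, W, scale)
                .transpose(0, 1, 3, 5, 2, 4)
                .reshape(N, C, H, W)
            )
            x._accumulate(gr)

    return _node(out_data, (x,), backward)


def upsample_nearest(x, scale: int):
    x = as_tensor(x)
    out_data = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        if x.requires_grad:
            N, C, H, W = x.shape
            x._accumulate(
                g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5))
            )

    return _node(out_data, (x,), backward)


_RESIZE_CACHE: dict = {}


def _resize_matrix(n_in: int, n_out: int, kernel: str) -> np.ndarray:
    key = (n_in, n_out, kernel)
    mat = _RESIZE_CACHE.get(key)
    if mat is None:
        from ..resample import resample_matrix
        mat = _RESIZE_CACHE.setdefault(key, resample_matrix(n_in, n_out, kernel))
    return mat


def resize_kernel(x, out_h: int, out_w: int, kernel: str = "linear"):
    """Separable spatial resampling of an NCHW batch to (out_h, out_w).

    The backward pass is the exact adjoint (transposed resampling matrices).
    """
    x = as_tensor(x)
    N, C, H, W = x.shape
    Ah = _resize_matrix(H, out_h, kernel)
    Aw = _resize_matrix(W, out_w, kernel)
    out_data = np.einsum("ph,nchw,qw->ncpq", Ah, x.data, Aw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.einsum("ph,ncpq,qw->nchw", Ah, g, Aw, optimize=True))

    return _node(out_data, (x,), backward)


def resize_linear(x, out_h: int, out_w: int):
    """Bilinear spatial resampling of an NCHW batch."""
    return resize_kernel(x, out_h, out_w, "linear")


def resize_cubic(x, out_h: int, out_w: int):
    """Keys bicubic spatial resampling of an NCHW batch."""
    return resize_kernel(x, out_h, out_w, "cubic")
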