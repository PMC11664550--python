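"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The detector's layers, losses and Grad-CAM++ all need vector–Jacobian
products through convolutions, bilinear resampling, attention and the box
geometry.  This module provides a small dynamic tape: a :class:`Tensor`
wraps an ``ndarray``, records the operation that produced it, and
``backward()`` walks the tape in reverse topological order.

Only the primitives the detector uses are implemented.  Convolution is
evaluated through ``im2col`` + ``einsum`` and differentiated with an
explicit ``col2im`` scatter; bilinear grid sampling and max pooling carry
hand-written adjoints.  Everything is float32 by default.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "as_tensor", "concatenate", "stack", "no_grad"]

_grad_enabled = True


class no_grad:
    """Context manager disabling tape recording (inference / assignment)."""

    def __enter__(self):
        global _grad_enabled
        self._prev = _grad_enabled
        _grad_enabled = False
        return self

    def __exit__(self, *exc):
        global _grad_enabled
        _grad_enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (adjoint of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd = grad.ndim - len(shape)
    if nd > 0:
        grad = grad.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")
    __array_priority__ = 100  # beat ndarray in mixed arithmetic

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        if isinstance(data, Tensor):
            data = data.data
        arr = np.asarray(data)
        self.data = arr if arr.dtype in (np.float32, np.float64) else arr.astype(np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents: tuple = ()
        self.name = name

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    # -- tape --------------------------------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad):
        grad = np.asarray(grad, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor._make(-self.data, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(-g)

        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data / other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g * self.data / (other.data ** 2), other.shape))

        out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = Tensor._make(self.data ** p, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = as_tensor(other)
        out = Tensor._make(self.data @ other.data, (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        out._backward = bw
        return out

    # -- elementwise nonlinearities ----------------------------------------
    def exp(self):
        y = np.exp(self.data)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = bw
        return out

    def log(self):
        out = Tensor._make(np.log(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / np.maximum(y, 1e-12))

        out._backward = bw
        return out

    def abs(self):
        out = Tensor._make(np.abs(self.data), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor._make(y, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bw
        return out

    def relu(self):
        mask = self.data > 0
        out = Tensor._make(self.data * mask, (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = bw
        return out

    def maximum(self, other):
        other = as_tensor(other)
        mask = self.data >= other.data  # ties route to self
        out = Tensor._make(np.maximum(self.data, other.data), (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (~mask), other.shape))

        out._backward = bw
        return out

    def minimum(self, other):
        other = as_tensor(other)
        mask = self.data <= other.data
        out = Tensor._make(np.minimum(self.data, other.data), (self, other), None)

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * mask, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * (~mask), other.shape))

        out._backward = bw
        return out

    # -- reductions / shape ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), None)

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims=False):
        y = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            if not self.requires_grad:
                return
            yk = self.data.max(axis=axis, keepdims=True)
            mask = (self.data == yk)
            mask = mask / mask.sum(axis=axis, keepdims=True)
            gk = g if (axis is None or keepdims) else np.expand_dims(g, axis)
            self._accum(mask * gk)

        out._backward = bw
        return out

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = Tensor._make(self.data.reshape(shape), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(self.data.transpose(axes), (self,), None)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor._make(self.data[idx], (self,), None)

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    def pad2d(self, pad: int, value: float = 0.0):
        """Constant-pad the trailing two (spatial) axes."""
        if pad == 0:
            return self
        pw = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor._make(np.pad(self.data, pw, constant_values=value), (self,), None)
        sl = (Ellipsis, slice(pad, pad + self.shape[-2]), slice(pad, pad + self.shape[-1]))

        def bw(g):
            if self.requires_grad:
                self._accum(g[sl])

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        y = e / e.sum(axis=axis, keepdims=True)
        out = Tensor._make(y, (self,), None)

        def bw(g):
            if self.requires_grad:
                dot = (g * y).sum(axis=axis, keepdims=True)
                self._accum(y * (g - dot))

        out._backward = bw
        return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def concatenate(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), None)
    sizes = [t.shape[axis] for t in tensors]
    offs = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offs[:-1], offs[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out._backward = bw
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = Tensor._make(np.stack([t.data for t in tensors], axis=axis), tuple(tensors), None)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out._backward = bw
    return out


# ---------------------------------------------------------------------------
# Structured primitives: convolution, pooling, bilinear grid sampling
# ---------------------------------------------------------------------------

def _im2col(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N,C,Hp,Wp) -> (N,C,Ho,Wo,kh,kw) window view (no copy)."""
    v = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def _col2im(cols: np.ndarray, xp_shape: tuple, kh: int, kw: int, stride: int) -> np.ndarray:
    """Adjoint of `_im2col`: scatter-add windows back onto the padded image."""
    n, c, ho, wo = cols.shape[:4]
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    for i in range(kh):
        for j in range(kw):
            xp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols[:, :, :, :, i, j]
    return xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int | None = None, groups: int = 1) -> Tensor:
    """2-D cross-correlation, NCHW layout.

    ``padding=None`` applies the house convention: k//2 zeros on every side,
    which is "same" at stride 1 and ceil(n/2) output at stride 2.
    Depthwise convolution is ``groups == C_in`` with ``w`` of shape
    (C, 1, kh, kw).
    """
    x = as_tensor(x)
    w = as_tensor(w)
    cout, cin_g, kh, kw = w.shape
    n, c, h, wid = x.shape
    if c != cin_g * groups:
        raise ValueError(f"channel mismatch: input has {c}, kernel expects {cin_g * groups}")
    pad = kh // 2 if padding is None else padding
    if kh == kw == 1 and stride == 1 and groups == 1 and pad == 0:
        return _conv1x1(x, w, b)
    xp = np.pad(x.data, [(0, 0), (0, 0), (pad, pad), (pad, pad)])
    cols = _im2col(xp, kh, kw, stride)              # (N,C,Ho,Wo,kh,kw)
    ho, wo = cols.shape[2], cols.shape[3]
    g = groups
    cols_g = cols.reshape(n, g, cin_g, ho, wo, kh, kw)
    w_g = w.data.reshape(g, cout // g, cin_g, kh, kw)
    y = np.einsum("ngchwij,gocij->ngohw", cols_g, w_g, optimize=True)
    y = np.ascontiguousarray(y.reshape(n, cout, ho, wo))
    if b is not None:
        y = y + as_tensor(b).data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    out = Tensor._make(y, parents, None)

    def bw(gy):
        gy_g = gy.reshape(n, g, cout // g, ho, wo)
        if w.requires_grad:
            gw = np.einsum("ngohw,ngchwij->gocij", gy_g, cols_g, optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            gcols = np.einsum("ngohw,gocij->ngchwij", gy_g, w_g, optimize=True)
            gxp = _col2im(gcols.reshape(n, c, ho, wo, kh, kw), xp.shape, kh, kw, stride)
            gx = gxp[:, :, pad:pad + h, pad:pad + wid] if pad else gxp
            x._accum(gx)
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(gy.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def unfold(x: Tensor, k: int, stride: int, padding: int = 0) -> Tensor:
    """Extract (possibly overlapping) k x k patches: (N,C,H,W) ->
    (N,C,nH,nW,k,k).  The adjoint scatter-adds patches back."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    cols = np.ascontiguousarray(_im2col(xp, k, k, stride))
    out = Tensor._make(cols, (x,), None)

    def bw(g):
        if x.requires_grad:
            gxp = _col2im(np.ascontiguousarray(g), xp.shape, k, k, stride)
            x._accum(gxp[:, :, padding:padding + h, padding:padding + w]
                     if padding else gxp)

    out._backward = bw
    return out


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Pointwise convolution as a single matrix product (fast path)."""
    n, c, h, wid = x.shape
    cout = w.shape[0]
    wm = w.data.reshape(cout, c)
    y = np.einsum("oc,nchw->nohw", wm, x.data, optimize=True)
    if b is not None:
        y = y + as_tensor(b).data.reshape(1, -1, 1, 1)
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    out = Tensor._make(y, parents, None)

    def bw(gy):
        if w.requires_grad:
            gw = np.einsum("nohw,nchw->oc", gy, x.data, optimize=True)
            w._accum(gw.reshape(w.shape))
        if x.requires_grad:
            x._accum(np.einsum("oc,nohw->nchw", wm, gy, optimize=True))
        if b is not None and parents[2].requires_grad:
            parents[2]._accum(gy.sum(axis=(0, 2, 3)))

    out._backward = bw
    return out


def batchnorm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float):
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns (y, batch_mean, batch_var) with the full BN adjoint (gradients
    flow through the batch statistics).
    """
    x = as_tensor(x)
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    gr = gamma.data.reshape(1, -1, 1, 1)
    y = xhat * gr + beta.data.reshape(1, -1, 1, 1)
    out = Tensor._make(y, (x, gamma, beta), None)

    def bw(gy):
        if beta.requires_grad:
            beta._accum(gy.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((gy * xhat).sum(axis=axes))
        if x.requires_grad:
            s1 = gy.sum(axis=axes, keepdims=True)
            s2 = (gy * xhat).sum(axis=axes, keepdims=True)
            x._accum((gr * inv / m) * (m * gy - s1 - xhat * s2))

    out._backward = bw
    return out, mu.ravel(), var.ravel()


def max_pool2d(x: Tensor, k: int, stride: int = 1, padding: int | None = None) -> Tensor:
    """Max pooling; default padding k//2 (shape-preserving at stride 1)."""
    x = as_tensor(x)
    pad = k // 2 if padding is None else padding
    n, c, h, w = x.shape
    xp = np.pad(x.data, [(0, 0), (0, 0), (pad, pad), (pad, pad)],
                constant_values=-np.inf)
    cols = _im2col(xp, k, k, stride)                # (N,C,Ho,Wo,k,k)
    ho, wo = cols.shape[2], cols.shape[3]
    flat = cols.reshape(n, c, ho, wo, k * k)
    arg = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
    out = Tensor._make(y, (x,), None)

    def bw(gy):
        if not x.requires_grad:
            return
        gcols = np.zeros_like(flat)
        np.put_along_axis(gcols, arg[..., None], gy[..., None], axis=-1)
        gxp = _col2im(gcols.reshape(n, c, ho, wo, k, k), xp.shape, k, k, stride)
        x._accum(gxp[:, :, pad:pad + h, pad:pad + w] if pad else gxp)

    out._backward = bw
    return out


def grid_sample_bilinear(x: Tensor, coords: Tensor) -> Tensor:
    """Bilinear resampling of ``x`` (N,C,H,W) at ``coords`` (N,Ho,Wo,2).

    Coordinates are (col, row) positions in input-pixel units under the
    half-pixel-center convention already resolved to array indices; they are
    clamped to the valid border before interpolation.
    """
    x = as_tensor(x)
    coords = as_tensor(coords)
    n, c, h, w = x.shape
    cx = np.clip(coords.data[..., 0], 0.0, w - 1.0)
    cy = np.clip(coords.data[..., 1], 0.0, h - 1.0)
    # interior mask for the grid adjoint: clamped coordinates have zero slope
    live_x = (coords.data[..., 0] > 0.0) & (coords.data[..., 0] < w - 1.0)
    live_y = (coords.data[..., 1] > 0.0) & (coords.data[..., 1] < h - 1.0)
    x0 = np.floor(cx).astype(np.int64)
    y0 = np.floor(cy).astype(np.int64)
    x0 = np.clip(x0, 0, w - 2) if w > 1 else x0 * 0
    y0 = np.clip(y0, 0, h - 2) if h > 1 else y0 * 0
    x1, y1 = x0 + (1 if w > 1 else 0), y0 + (1 if h > 1 else 0)
    fx, fy = cx - x0, cy - y0
    bi = np.arange(n)[:, None, None]
    g00 = x.data[bi, :, y0, x0]                     # (N,Ho,Wo,C)
    g01 = x.data[bi, :, y0, x1]
    g10 = x.data[bi, :, y1, x0]
    g11 = x.data[bi, :, y1, x1]
    wx, wy = fx[..., None], fy[..., None]
    y_out = (g00 * (1 - wy) * (1 - wx) + g01 * (1 - wy) * wx
             + g10 * wy * (1 - wx) + g11 * wy * wx)
    out = Tensor._make(np.moveaxis(y_out, -1, 1), (x, coords), None)

    def bw(gy):
        g = np.moveaxis(gy, 1, -1)                  # (N,Ho,Wo,C)
        if x.requires_grad:
            gx = np.zeros_like(x.data)
            np.add.at(gx, (bi, slice(None), y0, x0), np.moveaxis(g * (1 - wy) * (1 - wx), 0, 0))
            np.add.at(gx, (bi, slice(None), y0, x1), g * (1 - wy) * wx)
            np.add.at(gx, (bi, slice(None), y1, x0), g * wy * (1 - wx))
            np.add.at(gx, (bi, slice(None), y1, x1), g * wy * wx)
            x._accum(gx)
        if coords.requires_grad:
            dfx = ((g01 - g00) * (1 - wy) + (g11 - g10) * wy)
            dfy = ((g10 - g00) * (1 - wx) + (g11 - g01) * wx)
            gc = np.stack([(g * dfx).sum(-1) * live_x, (g * dfy).sum(-1) * live_y], axis=-1)
            coords._accum(gc)

    out._backward = bw
    return out
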