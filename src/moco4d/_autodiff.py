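"""Reverse-mode automatic differentiation on numpy arrays.

A small tape-based autodiff core providing exactly the operations needed by
this package: elementwise arithmetic, reductions, 3D convolution, instance
normalization, pooling/upsampling, separable box sums with replicate borders
(for windowed cross-correlation), and a trilinear spatial-transformer warp
that is differentiable with respect to the displacement field.

Tensors wrap ``numpy.ndarray`` data of any float dtype; every operation
preserves the promoted dtype of its inputs, so oracles can run the whole
graph in float64 while training runs in float32.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "conv3d",
    "avg_pool2",
    "upsample2",
    "leaky_relu",
    "instance_norm",
    "box_sum",
    "warp_tensor",
]


class Tensor:
    """Node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents",
                 "_grad_owned")

    def __init__(self, data, requires_grad=False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents = ()
        self._grad_owned = True

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def item(self):
        return self.data.item()

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accumulate(self, g):
        """Add a gradient contribution.

        Contributions are stored by reference on first arrival (backward
        closures never mutate the arrays they pass on, and a node's own
        gradient is final before it propagates, so aliasing is safe); a
        second contribution allocates a fresh owned sum.
        """
        if g.dtype != self.data.dtype:
            g = g.astype(self.data.dtype)
        if self.grad is None:
            self.grad = g
            self._grad_owned = False
        elif not self._grad_owned:
            self.grad = self.grad + g
            self._grad_owned = True
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        self._grad_owned = True
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- elementwise arithmetic ----------------------------------------
    # python scalars stay scalars (weak promotion): a float32 graph must
    # not be silently promoted to float64 by constants like `2.0 * x`.

    def __add__(self, other):
        if isinstance(other, (int, float)):
            def bwd(g):
                self._accumulate(g)

            return Tensor._make(self.data + other, (self,), bwd)
        other = as_tensor(other)
        out_data = self.data + other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g):
            self._accumulate(-g)

        return Tensor._make(-self.data, (self,), bwd)

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            def bwd(g):
                self._accumulate(g)

            return Tensor._make(self.data - other, (self,), bwd)
        other = as_tensor(other)
        out_data = self.data - other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    def __rsub__(self, other):
        if isinstance(other, (int, float)):
            def bwd(g):
                self._accumulate(-g)

            return Tensor._make(other - self.data, (self,), bwd)
        return as_tensor(other) - self

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            def bwd(g):
                self._accumulate(g * other)

            return Tensor._make(self.data * other, (self,), bwd)
        other = as_tensor(other)
        out_data = self.data * other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))

        return Tensor._make(out_data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return self * (1.0 / other)
        other = as_tensor(other)
        out_data = self.data / other.data

        def bwd(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / other.data**2, other.shape)
                )

        return Tensor._make(out_data, (self, other), bwd)

    def __rtruediv__(self, other):
        if isinstance(other, (int, float)):
            inv_data = other / self.data

            def bwd(g):
                self._accumulate(-g * inv_data / self.data)

            return Tensor._make(inv_data, (self,), bwd)
        return as_tensor(other) / self

    # -- shape manipulation --------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(g):
            self._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), bwd)

    def __getitem__(self, key):
        basic = isinstance(key, (slice, int)) or (
            isinstance(key, tuple)
            and all(isinstance(k, (slice, int)) for k in key)
        )

        def bwd(g):
            full = np.zeros(self.shape, dtype=g.dtype)
            if basic:
                full[key] += g
            else:
                np.add.at(full, key, g)
            self._accumulate(full)

        return Tensor._make(self.data[key], (self,), bwd)

    # -- reductions and simple nonlinearities --------------------------
    def sum(self, axis=None, keepdims=False):
        if axis is None and not keepdims:
            def bwd(g):
                self._accumulate(np.broadcast_to(g, self.shape))

            return Tensor._make(self.data.sum(), (self,), bwd)

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape))

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), bwd
        )

    def mean(self):
        n = self.data.size

        def bwd(g):
            self._accumulate(np.broadcast_to(g / n, self.shape))

        return Tensor._make(self.data.mean(), (self,), bwd)

    def sqrt(self):
        root = np.sqrt(self.data)

        def bwd(g):
            self._accumulate(g * 0.5 / np.maximum(root, np.finfo(root.dtype).tiny))

        return Tensor._make(root, (self,), bwd)

    def abs(self):
        def bwd(g):
            self._accumulate(g * np.sign(self.data))

        return Tensor._make(np.abs(self.data), (self,), bwd)

    def clamp_min(self, lo):
        mask = self.data >= lo
        out_data = np.where(mask, self.data, lo)

        def bwd(g):
            self._accumulate(g * mask)

        return Tensor._make(out_data, (self,), bwd)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


def concat(tensors, axis=0):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(out_data, tuple(tensors), bwd)


def leaky_relu(x, slope=0.2):
    x = as_tensor(x)
    mask = x.data >= 0
    out_data = np.where(mask, x.data, slope * x.data)

    def bwd(g):
        x._accumulate(g * np.where(mask, 1.0, slope).astype(g.dtype))

    return Tensor._make(out_data, (x,), bwd)


# ---------------------------------------------------------------------
# 3D convolution (stride 1, zero "same" padding)
# ---------------------------------------------------------------------

def _im2col(x, k):
    """(Cin,Z,Y,X) -> (Z*Y*X, Cin*k^3) patch matrix with zero same-padding."""
    cin, z, y, xx = x.shape
    r = k // 2
    xp = np.pad(x, ((0, 0), (r, r), (r, r), (r, r)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    # (Cin, Z, Y, X, k, k, k) -> (Z*Y*X, Cin*k^3)
    return np.ascontiguousarray(win.transpose(1, 2, 3, 0, 4, 5, 6)).reshape(
        z * y * xx, cin * k**3
    )


def _conv3d_raw(x, w, patches=None):
    """x (Cin,Z,Y,X), w (Cout,Cin,k,k,k) -> (Cout,Z,Y,X); zero same-padding."""
    cin, z, y, xx = x.shape
    cout, _, k, _, _ = w.shape
    if patches is None:
        patches = _im2col(x, k)
    out = patches @ w.reshape(cout, cin * k**3).T
    return np.ascontiguousarray(out.T).reshape(cout, z, y, xx)


def conv3d(x, w, b=None):
    """3D convolution (cross-correlation), stride 1, same zero padding.

    x: (Cin, Z, Y, X); w: (Cout, Cin, k, k, k); b: (Cout,) or None.
    """
    x, w = as_tensor(x), as_tensor(w)
    out_data = _conv3d_raw(x.data, w.data)
    if b is not None:
        b = as_tensor(b)
        out_data = out_data + b.data[:, None, None, None]
        parents = (x, w, b)
    else:
        parents = (x, w)
    cout, cin, k = w.shape[0], w.shape[1], w.shape[2]

    def bwd(g):
        if x.requires_grad:
            # dX = conv(g, w spatially flipped, channels transposed)
            wflip = np.ascontiguousarray(
                w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
            )
            x._accumulate(_conv3d_raw(g, wflip))
        if w.requires_grad:
            patches = _im2col(x.data, k)  # (P, Cin*k^3)
            gmat = g.reshape(cout, -1)  # (Cout, P)
            w._accumulate((gmat @ patches).reshape(cout, cin, k, k, k))
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(1, 2, 3)))

    return Tensor._make(out_data, parents, bwd)


# ---------------------------------------------------------------------
# Pooling / upsampling (factor 2, channels-first volumes)
# ---------------------------------------------------------------------

def avg_pool2(x):
    """Average pooling with kernel/stride 2 over the three spatial axes."""
    x = as_tensor(x)
    c, z, y, xx = x.shape
    if z % 2 or y % 2 or xx % 2:
        raise ValueError("avg_pool2 requires even spatial dimensions")
    v = x.data.reshape(c, z // 2, 2, y // 2, 2, xx // 2, 2)
    out_data = v.mean(axis=(2, 4, 6))

    def bwd(g):
        gb = np.broadcast_to(
            g[:, :, None, :, None, :, None] / 8.0,
            (c, z // 2, 2, y // 2, 2, xx // 2, 2),
        )
        x._accumulate(gb.reshape(c, z, y, xx))

    return Tensor._make(out_data, (x,), bwd)


def _up2_axis(a, axis):
    """Linear x2 upsample along axis (output i at input (i+0.5)/2 - 0.5)."""
    a = np.moveaxis(a, axis, 0)
    m = a.shape[0]
    out = np.empty((2 * m,) + a.shape[1:], dtype=a.dtype)
    if m == 1:
        out[0] = a[0]
        out[1] = a[0]
    else:
        ev, od = out[0::2], out[1::2]
        ev[0] = a[0]
        ev[1:] = 0.25 * a[:-1] + 0.75 * a[1:]
        od[:-1] = 0.75 * a[:-1] + 0.25 * a[1:]
        od[-1] = a[-1]
    return np.moveaxis(out, 0, axis)


def _up2_axis_adjoint(g, axis):
    g = np.moveaxis(g, axis, 0)
    m = g.shape[0] // 2
    ge, go = g[0::2], g[1::2]
    out = np.zeros((m,) + g.shape[1:], dtype=g.dtype)
    if m == 1:
        out[0] = ge[0] + go[0]
    else:
        out[0] += ge[0]
        out[1:] += 0.75 * ge[1:]
        out[:-1] += 0.25 * ge[1:]
        out[:-1] += 0.75 * go[:-1]
        out[1:] += 0.25 * go[:-1]
        out[-1] += go[-1]
    return np.moveaxis(out, 0, axis)


def upsample2(x):
    """Trilinear upsampling by a factor of 2 (half-pixel aligned)."""
    x = as_tensor(x)
    out_data = x.data
    for ax in (1, 2, 3):
        out_data = _up2_axis(out_data, ax)

    def bwd(g):
        for ax in (3, 2, 1):
            g = _up2_axis_adjoint(g, ax)
        x._accumulate(g)

    return Tensor._make(out_data, (x,), bwd)


# ---------------------------------------------------------------------
# Instance normalization
# ---------------------------------------------------------------------

def instance_norm(x, gamma, beta, eps=1e-5):
    """Per-channel normalization over spatial axes with affine parameters."""
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    ax = tuple(range(1, x.data.ndim))
    mu = x.data.mean(axis=ax, keepdims=True)
    var = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (x.shape[0],) + (1,) * (x.data.ndim - 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)
    n = np.prod([x.shape[i] for i in ax])

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=ax))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=ax))
        if x.requires_grad:
            gx_hat = g * gamma.data.reshape(gshape)
            t1 = gx_hat.sum(axis=ax, keepdims=True)
            t2 = (gx_hat * xhat).sum(axis=ax, keepdims=True)
            x._accumulate(inv * (gx_hat - (t1 + xhat * t2) / n))

    return Tensor._make(out_data, (x, gamma, beta), bwd)


# ---------------------------------------------------------------------
# Separable box sum with replicate borders
# ---------------------------------------------------------------------

def _box1d(a, n, axis):
    """Window sum of size n along axis with replicate padding."""
    return uniform_filter1d(a, size=n, axis=axis, mode="nearest") * n


def _box1d_adjoint(g, n, axis):
    """Adjoint of `_box1d` (fold border contributions onto edge samples)."""
    r = n // 2
    g = np.moveaxis(g, axis, 0)
    m = g.shape[0]
    pad = np.zeros((m + 2 * r,) + g.shape[1:], dtype=g.dtype)
    pad[r:r + m] = g
    # full correlation with a ones kernel on the zero-extended array
    t = uniform_filter1d(pad, size=n, axis=0, mode="constant") * n
    out = t[r:r + m].copy()
    out[0] += t[:r].sum(axis=0)
    out[-1] += t[r + m:].sum(axis=0)
    return np.moveaxis(out, 0, axis)


def box_sum(x, n):
    """Sum over the n^3 window centred at each voxel, replicate borders.

    Acts on the trailing three axes of ``x``.
    """
    x = as_tensor(x)
    nd = x.data.ndim
    axes = (nd - 3, nd - 2, nd - 1)
    out_data = x.data
    for ax in axes:
        out_data = _box1d(out_data, n, ax)

    def bwd(g):
        for ax in reversed(axes):
            g = _box1d_adjoint(g, n, ax)
        x._accumulate(g)

    return Tensor._make(out_data, (x,), bwd)


# ---------------------------------------------------------------------
# Spatial transformer: trilinear warp, differentiable w.r.t. displacement
# ---------------------------------------------------------------------

def _gather_trilinear(img, zc, yc, xc):
    """Trilinear sample of img at (zc,yc,xc) with border replication.

    Returns (values, dval/dz, dval/dy, dval/dx).
    """
    nz, ny, nx = img.shape
    zc = np.clip(zc, 0.0, nz - 1.0)
    yc = np.clip(yc, 0.0, ny - 1.0)
    xc = np.clip(xc, 0.0, nx - 1.0)
    z0 = np.minimum(np.floor(zc).astype(np.int64), nz - 2) if nz > 1 else np.zeros_like(zc, np.int64)
    y0 = np.minimum(np.floor(yc).astype(np.int64), ny - 2) if ny > 1 else np.zeros_like(yc, np.int64)
    x0 = np.minimum(np.floor(xc).astype(np.int64), nx - 2) if nx > 1 else np.zeros_like(xc, np.int64)
    dz1 = 1 if nz > 1 else 0
    dy1 = 1 if ny > 1 else 0
    dx1 = 1 if nx > 1 else 0
    fz = (zc - z0).astype(img.dtype, copy=False)
    fy = (yc - y0).astype(img.dtype, copy=False)
    fx = (xc - x0).astype(img.dtype, copy=False)

    # flat indexing: one gather per corner on the raveled image
    flat = img.ravel()
    base = (z0 * ny + y0) * nx + x0
    c000 = flat[base]
    c001 = flat[base + dx1]
    c010 = flat[base + dy1 * nx]
    c011 = flat[base + dy1 * nx + dx1]
    zoff = dz1 * ny * nx
    c100 = flat[base + zoff]
    c101 = flat[base + zoff + dx1]
    c110 = flat[base + zoff + dy1 * nx]
    c111 = flat[base + zoff + dy1 * nx + dx1]

    c00 = c000 * (1 - fx) + c001 * fx
    c01 = c010 * (1 - fx) + c011 * fx
    c10 = c100 * (1 - fx) + c101 * fx
    c11 = c110 * (1 - fx) + c111 * fx
    c0 = c00 * (1 - fy) + c01 * fy
    c1 = c10 * (1 - fy) + c11 * fy
    val = c0 * (1 - fz) + c1 * fz

    dval_dz = c1 - c0
    dval_dy = (c01 - c00) * (1 - fz) + (c11 - c10) * fz
    dx00 = c001 - c000
    dx01 = c011 - c010
    dx10 = c101 - c100
    dx11 = c111 - c110
    dval_dx = ((dx00 * (1 - fy) + dx01 * fy) * (1 - fz)
               + (dx10 * (1 - fy) + dx11 * fy) * fz)
    return val, dval_dz, dval_dy, dval_dx


def warp_tensor(img, disp):
    """Warp a 3D image by a displacement field (pull convention).

    ``out(p) = img(p + disp(p))`` with trilinear interpolation and replicate
    borders.  ``img`` is a constant ndarray (Z,Y,X); ``disp`` is a Tensor of
    shape (3,Z,Y,X) with components ordered (dx, dy, dz) in voxel units on
    the (Z,Y,X) index axes — dx displaces the fastest (X) axis.
    """
    disp = as_tensor(disp)
    img = np.asarray(img)
    nz, ny, nx = img.shape
    gz, gy, gx = np.meshgrid(
        np.arange(nz, dtype=disp.data.dtype),
        np.arange(ny, dtype=disp.data.dtype),
        np.arange(nx, dtype=disp.data.dtype),
        indexing="ij",
    )
    zc = gz + disp.data[2]
    yc = gy + disp.data[1]
    xc = gx + disp.data[0]
    # clamped samples have zero derivative w.r.t. the displacement
    mz = (zc >= 0.0) & (zc <= nz - 1.0)
    my = (yc >= 0.0) & (yc <= ny - 1.0)
    mx = (xc >= 0.0) & (xc <= nx - 1.0)
    val, dz, dy, dx = _gather_trilinear(img, zc, yc, xc)
    dz, dy, dx = dz * mz, dy * my, dx * mx

    def bwd(g):
        grad = np.stack([g * dx, g * dy, g * dz], axis=0)
        disp._accumulate(grad)

    return Tensor._make(val, (disp,), bwd)
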