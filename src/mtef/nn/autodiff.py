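"""Minimal reverse-mode automatic differentiation on numpy arrays.

The engine is deliberately small: a :class:`Tensor` wraps an ``ndarray``,
every operation records a closure that propagates the upstream gradient to
its parents, and :meth:`Tensor.backward` walks the graph in reverse
topological order.  Only the operations needed by the registration networks
are implemented (elementwise algebra, matmul, shape surgery, softmax,
layer normalisation, 3D convolution via im2col, trilinear grid sampling and
resizing).  Everything is single-threaded, deterministic numpy.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the ``with`` block."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
            # free intermediate graph memory eagerly
            if node is not self:
                node._backward = None

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # ------------------------------------------------------------- operators
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(other, -1.0))

    def __rsub__(self, other):
        return add(mul(self, -1.0), other)

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return mul(self, power(other, -1.0))
        return mul(self, 1.0 / other)

    def __neg__(self):
        return mul(self, -1.0)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape if len(shape) > 1 else shape[0])

    def transpose(self, axes):
        return transpose(self, axes)

    def sum(self, axis=None, keepdims=False):
        return reduce_sum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return reduce_mean(self, axis, keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    req = _grad_enabled and any(p.requires_grad for p in parents)
    if req:
        out.requires_grad = True
        out._parents = tuple(p for p in parents if p.requires_grad)
        out._backward = backward
    return out


# ---------------------------------------------------------------- elementwise
def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), bwd)


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accum(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), bwd)


def power(a, p: float):
    a = as_tensor(a)
    data = a.data**p

    def bwd(g):
        if a.requires_grad:
            a._accum(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), bwd)


def sqrt(a):
    a = as_tensor(a)
    data = np.sqrt(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * 0.5 / np.maximum(data, 1e-12))

    return _make(data, (a,), bwd)


def exp(a):
    a = as_tensor(a)
    data = np.exp(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * data)

    return _make(data, (a,), bwd)


def absolute(a):
    a = as_tensor(a)
    data = np.abs(a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * np.sign(a.data))

    return _make(data, (a,), bwd)


def clip_min(a, lo: float):
    """max(a, lo); gradient passes where a >= lo."""
    a = as_tensor(a)
    mask = a.data >= lo
    data = np.maximum(a.data, lo)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(data, (a,), bwd)


def relu(a):
    a = as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def bwd(g):
        if a.requires_grad:
            a._accum(g * mask)

    return _make(data, (a,), bwd)


def leaky_relu(a, slope: float = 0.2):
    a = as_tensor(a)
    mask = a.data > 0
    data = np.where(mask, a.data, slope * a.data)

    def bwd(g):
        if a.requires_grad:
            a._accum(g * np.where(mask, 1.0, slope).astype(np.float32))

    return _make(data, (a,), bwd)


# ------------------------------------------------------------------ reshaping
def reshape(a, shape):
    a = as_tensor(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def bwd(g):
        if a.requires_grad:
            a._accum(g.reshape(old))

    return _make(data, (a,), bwd)


def transpose(a, axes):
    a = as_tensor(a)
    data = np.ascontiguousarray(a.data.transpose(axes))
    inv = np.argsort(axes)

    def bwd(g):
        if a.requires_grad:
            a._accum(g.transpose(inv))

    return _make(data, (a,), bwd)


def concat(tensors: Iterable[Tensor], axis: int = 0):
    ts = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return _make(data, ts, bwd)


def getitem(a, idx):
    a = as_tensor(a)
    data = a.data[idx]

    def bwd(g):
        if a.requires_grad:
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

    return _make(data, (a,), bwd)


def pad(a, pad_width):
    """Zero padding. ``pad_width`` as for ``np.pad``."""
    a = as_tensor(a)
    data = np.pad(a.data, pad_width)
    slices = tuple(slice(lo, lo + s) for (lo, _), s in zip(pad_width, a.data.shape))

    def bwd(g):
        if a.requires_grad:
            a._accum(g[slices])

    return _make(data, (a,), bwd)


def roll(a, shift, axis):
    a = as_tensor(a)
    data = np.roll(a.data, shift, axis=axis)
    neg = tuple(-s for s in shift) if isinstance(shift, (tuple, list)) else -shift

    def bwd(g):
        if a.requires_grad:
            a._accum(np.roll(g, neg, axis=axis))

    return _make(data, (a,), bwd)


# ----------------------------------------------------------------- reductions
def reduce_sum(a, axis=None, keepdims=False):
    a = as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        if not a.requires_grad:
            return
        g = np.asarray(g)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        a._accum(np.broadcast_to(g, a.data.shape).astype(np.float32))

    return _make(data, (a,), bwd)


def reduce_mean(a, axis=None, keepdims=False):
    a = as_tensor(a)
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
    )
    return mul(reduce_sum(a, axis, keepdims), 1.0 / float(n))


# -------------------------------------------------------------------- matmul
def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            ga = g @ b.data.swapaxes(-1, -2)
            a._accum(_unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = a.data.swapaxes(-1, -2) @ g
            b._accum(_unbroadcast(gb, b.data.shape))

    return _make(data, (a, b), bwd)


# ------------------------------------------------------------ fused softmax/LN
def softmax(a, axis: int = -1, mask: np.ndarray | None = None):
    """Softmax along ``axis``; ``mask`` (additive, e.g. -1e9) is a constant."""
    a = as_tensor(a)
    z = a.data if mask is None else a.data + mask
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    data = e / e.sum(axis=axis, keepdims=True)

    def bwd(g):
        if a.requires_grad:
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accum(data * (g - dot))

    return _make(data, (a,), bwd)


def layer_norm(a, eps: float = 1e-5):
    """Normalise over the last axis to zero mean / unit variance."""
    a = as_tensor(a)
    mu = a.data.mean(axis=-1, keepdims=True)
    xc = a.data - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    data = xc * inv

    def bwd(g):
        if a.requires_grad:
            n = a.data.shape[-1]
            gx = inv * (
                g
                - g.mean(axis=-1, keepdims=True)
                - data * (g * data).mean(axis=-1, keepdims=True)
            )
            a._accum(gx.astype(np.float32))

    return _make(data, (a,), bwd)


# -------------------------------------------------------------- 3D convolution
def _im2col_indices(shape, k, stride, padding):
    H, W, L = shape
    Ho = (H + 2 * padding - k) // stride + 1
    Wo = (W + 2 * padding - k) // stride + 1
    Lo = (L + 2 * padding - k) // stride + 1
    return Ho, Wo, Lo


def conv3d(x, w, b=None, stride: int = 1, padding: int = 1):
    """3D convolution. x: (N,C,H,W,L); w: (Cout,Cin,k,k,k); b: (Cout,)."""
    x, w = as_tensor(x), as_tensor(w)
    N, C, H, W, L = x.data.shape
    Cout, Cin, k, _, _ = w.data.shape
    assert Cin == C, f"channel mismatch {Cin} vs {C}"
    Ho, Wo, Lo = _im2col_indices((H, W, L), k, stride, padding)

    xp = x.data
    if padding:
        xp = np.pad(xp, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    # strided sliding-window view -> columns
    s = xp.strides
    win = np.lib.stride_tricks.as_strided(
        xp,
        shape=(N, C, Ho, Wo, Lo, k, k, k),
        strides=(s[0], s[1], s[2] * stride, s[3] * stride, s[4] * stride, s[2], s[3], s[4]),
        writeable=False,
    )
    cols = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(N * Ho * Wo * Lo, C * k**3)
    wmat = w.data.reshape(Cout, C * k**3)
    out = cols @ wmat.T
    if b is not None:
        out = out + as_tensor(b).data
    data = out.reshape(N, Ho, Wo, Lo, Cout).transpose(0, 4, 1, 2, 3)

    bt = as_tensor(b) if b is not None else None

    def bwd(g):
        gmat = g.transpose(0, 2, 3, 4, 1).reshape(N * Ho * Wo * Lo, Cout)
        if w.requires_grad:
            gw = gmat.T @ cols
            w._accum(gw.reshape(w.data.shape))
        if bt is not None and bt.requires_grad:
            bt._accum(gmat.sum(axis=0))
        if x.requires_grad:
            gcols = gmat @ wmat  # (NHoWoLo, C k^3)
            gx = np.zeros_like(xp)
            gc = gcols.reshape(N, Ho, Wo, Lo, C, k, k, k)
            # scatter-add each kernel offset as a strided slice (fast, no add.at)
            for di in range(k):
                for dj in range(k):
                    for dl in range(k):
                        gx[
                            :,
                            :,
                            di : di + Ho * stride : stride,
                            dj : dj + Wo * stride : stride,
                            dl : dl + Lo * stride : stride,
                        ] += gc[:, :, :, :, :, di, dj, dl].transpose(0, 4, 1, 2, 3)
            if padding:
                gx = gx[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accum(gx)

    parents = (x, w) if bt is None else (x, w, bt)
    return _make(data, parents, bwd)


def _box_sum_valid(a: np.ndarray, ks) -> np.ndarray:
    """Sum over all k₀×k₁×k₂ windows (valid mode) via cumulative sums."""
    for ax, k in enumerate(ks):
        if k == 1:
            continue
        c = np.cumsum(a, axis=ax, dtype=np.float64)
        zshape = list(c.shape)
        zshape[ax] = 1
        c = np.concatenate([np.zeros(zshape), c], axis=ax)
        n = a.shape[ax]
        hi = [slice(None)] * a.ndim
        lo = [slice(None)] * a.ndim
        hi[ax] = slice(k, n + 1)
        lo[ax] = slice(0, n + 1 - k)
        a = c[tuple(hi)] - c[tuple(lo)]
    return np.asarray(a, dtype=np.float64)


def box_filter_valid(t, k):
    """Mean over every fully-contained window (valid mode) of a (H,W,L)
    tensor; ``k`` is an int or per-axis triple.

    The backward pass is the transpose: a valid box-sum of the zero-padded
    upstream gradient.
    """
    t = as_tensor(t)
    ks = (k, k, k) if np.isscalar(k) else tuple(k)
    inv = 1.0 / float(np.prod(ks))
    data = _box_sum_valid(t.data, ks) * inv

    def bwd(g):
        if t.requires_grad:
            gp = np.pad(np.asarray(g, dtype=np.float64),
                        [(kk - 1, kk - 1) for kk in ks])
            t._accum((_box_sum_valid(gp, ks) * inv).astype(np.float32))

    return _make(data, (t,), bwd)


# ---------------------------------------------------- trilinear sampling ops
def _sample_setup(field_data, shape):
    """Return corner indices and weights for x + u(x) sampling."""
    H, W, L = shape
    gx, gy, gz = np.meshgrid(
        np.arange(H, dtype=np.float32),
        np.arange(W, dtype=np.float32),
        np.arange(L, dtype=np.float32),
        indexing="ij",
    )
    px = gx + field_data[0]
    py = gy + field_data[1]
    pz = gz + field_data[2]
    # inside-volume masks: the border clamp makes the true derivative zero
    # with respect to the field wherever the sample position was clipped
    inside = (
        (px > 0) & (px < H - 1),
        (py > 0) & (py < W - 1),
        (pz > 0) & (pz < L - 1),
    )
    return _interp_setup(px, py, pz, shape), inside


def _interp_setup(px, py, pz, shape):
    H, W, L = shape
    px = np.clip(px, 0.0, H - 1.0)
    py = np.clip(py, 0.0, W - 1.0)
    pz = np.clip(pz, 0.0, L - 1.0)
    x0 = np.floor(px).astype(np.int64)
    y0 = np.floor(py).astype(np.int64)
    z0 = np.floor(pz).astype(np.int64)
    x0 = np.minimum(x0, H - 2) if H > 1 else np.zeros_like(x0)
    y0 = np.minimum(y0, W - 2) if W > 1 else np.zeros_like(y0)
    z0 = np.minimum(z0, L - 2) if L > 1 else np.zeros_like(z0)
    fx = px - x0
    fy = py - y0
    fz = pz - z0
    return (x0, y0, z0, fx, fy, fz)


def _gather_trilinear(vol, setup):
    """vol: (C,H,W,L); returns (C, *grid) interpolated values."""
    C, H, W, L = vol.shape
    x0, y0, z0, fx, fy, fz = setup
    x1 = np.minimum(x0 + 1, H - 1)
    y1 = np.minimum(y0 + 1, W - 1)
    z1 = np.minimum(z0 + 1, L - 1)
    out = None
    for xi, wx in ((x0, 1 - fx), (x1, fx)):
        for yi, wy in ((y0, 1 - fy), (y1, fy)):
            for zi, wz in ((z0, 1 - fz), (z1, fz)):
                w = wx * wy * wz
                v = vol[:, xi, yi, zi] * w[None]
                out = v if out is None else out + v
    return out


def warp3d(img, field):
    """Trilinear backward warp: out(x) = img(x + field(x)).

    img: Tensor or array (C,H,W,L); field: Tensor (3,H,W,L) in voxel units.
    Differentiable with respect to both the image and the field; sampling
    outside the volume clamps to the border.
    """
    img = as_tensor(img)
    field = as_tensor(field)
    C, H, W, L = img.data.shape
    setup, inside = _sample_setup(field.data, (H, W, L))
    x0, y0, z0, fx, fy, fz = setup
    x1 = np.minimum(x0 + 1, H - 1)
    y1 = np.minimum(y0 + 1, W - 1)
    z1 = np.minimum(z0 + 1, L - 1)
    data = _gather_trilinear(img.data, setup)

    def bwd(g):
        if img.requires_grad:
            gi = np.zeros_like(img.data)
            flatshape = (C, -1)
            size = H * W * L
            for xi, wx in ((x0, 1 - fx), (x1, fx)):
                for yi, wy in ((y0, 1 - fy), (y1, fy)):
                    for zi, wz in ((z0, 1 - fz), (z1, fz)):
                        idx = (xi * W + yi) * L + zi
                        wgt = (wx * wy * wz).ravel()
                        contrib = (g.reshape(flatshape) * wgt[None]).astype(np.float64)
                        for c in range(C):
                            gi.reshape(flatshape)[c] += np.bincount(
                                idx.ravel(), weights=contrib[c], minlength=size
                            ).astype(np.float32)
            img._accum(gi)
        if field.requires_grad:
            vol = img.data
            # d out / d p via differences of corner values
            def corner(xi, yi, zi):
                return vol[:, xi, yi, zi]

            c000 = corner(x0, y0, z0)
            c100 = corner(x1, y0, z0)
            c010 = corner(x0, y1, z0)
            c110 = corner(x1, y1, z0)
            c001 = corner(x0, y0, z1)
            c101 = corner(x1, y0, z1)
            c011 = corner(x0, y1, z1)
            c111 = corner(x1, y1, z1)
            dx = ((c100 - c000) * (1 - fy) * (1 - fz)
                  + (c110 - c010) * fy * (1 - fz)
                  + (c101 - c001) * (1 - fy) * fz
                  + (c111 - c011) * fy * fz)
            dy = ((c010 - c000) * (1 - fx) * (1 - fz)
                  + (c110 - c100) * fx * (1 - fz)
                  + (c011 - c001) * (1 - fx) * fz
                  + (c111 - c101) * fx * fz)
            dz = ((c001 - c000) * (1 - fx) * (1 - fy)
                  + (c101 - c100) * fx * (1 - fy)
                  + (c011 - c010) * (1 - fx) * fy
                  + (c111 - c110) * fx * fy)
            gf = np.stack(
                [
                    (g * dx).sum(axis=0) * inside[0],
                    (g * dy).sum(axis=0) * inside[1],
                    (g * dz).sum(axis=0) * inside[2],
                ]
            )
            field._accum(gf.astype(np.float32))

    return _make(data, (img, field), bwd)


def resize3(t, target_shape, scale: float = 1.0):
    """Trilinear resize of (C,H,W,L) to (C,*target_shape), values × scale.

    Uses endpoint-preserving (align-corners) coordinates; the backward pass
    is the transpose scatter.
    """
    t = as_tensor(t)
    C, H, W, L = t.data.shape
    Ht, Wt, Lt = target_shape

    def coords(n_src, n_dst):
        if n_dst == 1:
            return np.zeros(1, dtype=np.float32)
        return np.linspace(0.0, n_src - 1.0, n_dst, dtype=np.float32)

    px, py, pz = np.meshgrid(
        coords(H, Ht), coords(W, Wt), coords(L, Lt), indexing="ij"
    )
    setup = _interp_setup(px, py, pz, (H, W, L))
    x0, y0, z0, fx, fy, fz = setup
    x1 = np.minimum(x0 + 1, H - 1)
    y1 = np.minimum(y0 + 1, W - 1)
    z1 = np.minimum(z0 + 1, L - 1)
    data = _gather_trilinear(t.data, setup) * scale

    def bwd(g):
        if not t.requires_grad:
            return
        gi = np.zeros((C, H * W * L), dtype=np.float64)
        for xi, wx in ((x0, 1 - fx), (x1, fx)):
            for yi, wy in ((y0, 1 - fy), (y1, fy)):
                for zi, wz in ((z0, 1 - fz), (z1, fz)):
                    idx = ((xi * W + yi) * L + zi).ravel()
                    wgt = (wx * wy * wz).ravel() * scale
                    gflat = g.reshape(C, -1)
                    for c in range(C):
                        gi[c] += np.bincount(
                            idx, weights=gflat[c] * wgt, minlength=H * W * L
                        )
        t._accum(gi.reshape(t.data.shape).astype(np.float32))

    return _make(data, (t,), bwd)


def stack(tensors, axis=0):
    ts = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in ts], axis=axis)

    def bwd(g):
        gs = np.moveaxis(g, axis, 0)
        for i, t in enumerate(ts):
            if t.requires_grad:
                t._accum(gs[i])

    return _make(data, ts, bwd)
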