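"""Network building blocks on top of the autodiff engine.

Channels-last grids ``(H, W, L, C)`` are used inside the attention encoder
(token algebra is cheaper that way); convolutional pieces use channels-first
``(N, C, H, W, L)``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Tiny module base: parameter discovery by attribute walk."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen = set()

        def walk(obj):
            if isinstance(obj, Parameter):
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    walk(v)

        walk(self)
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)}"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data[...] = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _xavier(rng, fan_in, fan_out, shape):
    bound = float(np.sqrt(6.0 / (fan_in + fan_out)))
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 zero_init: bool = False, bias: bool = True):
        if zero_init:
            w = np.zeros((d_in, d_out), dtype=np.float32)
        else:
            w = _xavier(rng, d_in, d_out, (d_in, d_out))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(d_out, dtype=np.float32)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int):
        self.gamma = Parameter(np.ones(dim, dtype=np.float32))
        self.beta = Parameter(np.zeros(dim, dtype=np.float32))

    def forward(self, x):
        return ad.layer_norm(x) * self.gamma + self.beta


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, zero_init: bool = False):
        if padding is None:
            padding = k // 2
        fan_in = c_in * k**3
        if zero_init:
            w = np.zeros((c_out, c_in, k, k, k), dtype=np.float32)
        else:
            w = _xavier(rng, fan_in, c_out * k**3, (c_out, c_in, k, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32))
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return ad.conv3d(x, self.weight, self.bias, self.stride, self.padding)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng):
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.fc2(ad.relu(self.fc1(x)))


# --------------------------------------------------------- window attention
def _window_partition(x, win):
    """(H,W,L,C) -> (nW, T, C) tokens per window; returns also grid dims."""
    H, W, L, C = x.shape
    wh, ww, wl = win
    nh, nw, nl = H // wh, W // ww, L // wl
    x = ad.reshape(x, (nh, wh, nw, ww, nl, wl, C))
    x = ad.transpose(x, (0, 2, 4, 1, 3, 5, 6))
    return ad.reshape(x, (nh * nw * nl, wh * ww * wl, C)), (nh, nw, nl)


def _window_reverse(tokens, win, grid, C):
    wh, ww, wl = win
    nh, nw, nl = grid
    x = ad.reshape(tokens, (nh, nw, nl, wh, ww, wl, C))
    x = ad.transpose(x, (0, 3, 1, 4, 2, 5, 6))
    return ad.reshape(x, (nh * wh, nw * ww, nl * wl, C))


def _shift_mask(shape, win, shifts):
    """Additive attention mask (nW, T, T) for cyclically shifted windows."""
    H, W, L = shape
    ids = np.zeros((H, W, L), dtype=np.int64)
    cnt = 0
    ranges = []
    for n, w, s in zip((H, W, L), win, shifts):
        if s == 0:
            ranges.append([slice(0, n)])
        else:
            ranges.append([slice(0, n - w), slice(n - w, n - s), slice(n - s, n)])
    for rx in ranges[0]:
        for ry in ranges[1]:
            for rz in ranges[2]:
                ids[rx, ry, rz] = cnt
                cnt += 1
    wh, ww, wl = win
    nh, nw, nl = H // wh, W // ww, L // wl
    ids = ids.reshape(nh, wh, nw, ww, nl, wl).transpose(0, 2, 4, 1, 3, 5)
    ids = ids.reshape(nh * nw * nl, wh * ww * wl)
    mask = (ids[:, :, None] != ids[:, None, :]).astype(np.float32) * -1e9
    return mask


class WindowAttention(Module):
    """Multi-head self-attention inside (optionally shifted) local windows.

    No positional term of any kind: registration losses are spatial, so the
    network does not need one, and dropping it keeps the block lean.
    """

    def __init__(self, dim: int, heads: int, rng):
        self.heads = heads
        self.dim = dim
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x, win, shifts):
        H, W, L, C = x.shape
        shifted = any(s > 0 for s in shifts)
        if shifted:
            x = ad.roll(x, tuple(-s for s in shifts), axis=(0, 1, 2))
        tokens, grid = _window_partition(x, win)
        nW, T, _ = tokens.shape
        h = self.heads
        dh = C // h
        qkv = self.qkv(tokens)  # (nW, T, 3C)
        qkv = ad.reshape(qkv, (nW, T, 3, h, dh))
        qkv = ad.transpose(qkv, (2, 0, 3, 1, 4))  # (3, nW, h, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = ad.matmul(q, ad.transpose(k, (0, 1, 3, 2))) * (1.0 / np.sqrt(dh))
        mask = None
        if shifted:
            mask = _shift_mask((H, W, L), win, shifts)[:, None, :, :]
        attn = ad.softmax(scores, axis=-1, mask=mask)
        out = ad.matmul(attn, v)  # (nW, h, T, dh)
        out = ad.reshape(ad.transpose(out, (0, 2, 1, 3)), (nW, T, C))
        out = self.proj(out)
        x = _window_reverse(out, win, grid, C)
        if shifted:
            x = ad.roll(x, shifts, axis=(0, 1, 2))
        return x


class SwinBlock(Module):
    """Pre-norm windowed-attention block with residual connections."""

    def __init__(self, dim: int, heads: int, rng, mlp_ratio: float = 2.0):
        self.norm1 = LayerNorm(dim)
        self.attn = WindowAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.mlp = Mlp(dim, int(dim * mlp_ratio), rng)

    def forward(self, x, win, shifts):
        x = x + self.attn(self.norm1(x), win, shifts)
        x = x + self.mlp(self.norm2(x))
        return x


class PatchMerging(Module):
    """Concatenate 2×2×2 neighbours and project 8C -> 2C (halves resolution)."""

    def __init__(self, dim: int, rng):
        self.proj = Linear(8 * dim, 2 * dim, rng)

    def forward(self, x):
        H, W, L, C = x.shape
        ph, pw, pl = H % 2, W % 2, L % 2
        if ph or pw or pl:
            x = ad.pad(x, ((0, ph), (0, pw), (0, pl), (0, 0)))
            H, W, L = H + ph, W + pw, L + pl
        x = ad.reshape(x, (H // 2, 2, W // 2, 2, L // 2, 2, C))
        x = ad.transpose(x, (0, 2, 4, 1, 3, 5, 6))
        x = ad.reshape(x, (H // 2, W // 2, L // 2, 8 * C))
        return self.proj(x)


class ConvStage(Module):
    """CNN substitute for an attention stage (encoder-ablation variant)."""

    def __init__(self, dim: int, depth: int, rng):
        self.convs = [Conv3d(dim, dim, 3, rng) for _ in range(depth)]

    def forward(self, x):  # x channels-last (H,W,L,C)
        t = ad.transpose(x, (3, 0, 1, 2))
        t = ad.reshape(t, (1,) + t.shape)
        for conv in self.convs:
            t = t + ad.leaky_relu(conv(t))
        t = ad.reshape(t, t.shape[1:])
        return ad.transpose(t, (1, 2, 3, 0))


class ResBlock3d(Module):
    """Two-convolution residual block (channels-first)."""

    def __init__(self, c: int, rng):
        self.conv1 = Conv3d(c, c, 3, rng)
        self.conv2 = Conv3d(c, c, 3, rng)

    def forward(self, x):
        h = ad.relu(self.conv1(x))
        return ad.relu(x + self.conv2(h))
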