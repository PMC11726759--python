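"""Shared pyramid registration network (SPR-Net).

Two *independent* hierarchical windowed-attention encoders — one per
modality, sharing architecture but not parameters — feed a *shared*
convolutional pyramid decoder that predicts a displacement field coarse to
fine.  Patch embedding carries no positional term: the registration loss is
itself spatial, so absolute position information is unnecessary.

The decoder starts from the deepest features of both modalities, emits a
coarse field, then at each finer level upsamples the running field (×2 grid
and ×2 magnitude, since displacements are stored in voxel units), warps the
moving features with it, concatenates the fixed features (plus the
upsampled decoder state when skip connections are enabled) and applies
3×3×3 convolutions to predict a refinement that is composed onto the
running field.  Refinement heads are zero-initialised so an untrained
network is exactly the identity transform — this keeps the four-stage
cascade stable at the start of training.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from functools import lru_cache

import numpy as np

from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import (Conv3d, ConvStage, Linear, Module, PatchMerging,
                        SwinBlock)


@dataclass
class NetConfig:
    patch_size: int = 2
    embed_dim: int = 16
    depths: tuple[int, ...] = (2, 2, 6, 2)   # 12 attention layers in total
    window: int = 4
    heads: tuple[int, ...] = (2, 4, 4, 8)
    use_skip: bool = True
    encoder: str = "attention"               # or "cnn" (ablation)
    decoder_hidden: int = 16
    decoder_depth: int = 1                   # mix convolutions per level
    seed: int = 0

    def __post_init__(self):
        if len(self.heads) < len(self.depths):
            raise ValueError("need a head count per stage")
        if self.encoder not in ("attention", "cnn"):
            raise ValueError(f"unknown encoder kind {self.encoder!r}")
        for s in range(len(self.depths)):
            if (self.embed_dim * 2**s) % self.heads[s] != 0:
                raise ValueError(f"heads must divide channels at stage {s}")

    @property
    def n_stages(self) -> int:
        return len(self.depths)

    def stage_dim(self, s: int) -> int:
        return self.embed_dim * 2**s

    def validate_shape(self, shape):
        for ax, s in enumerate(shape):
            if s % self.patch_size != 0:
                raise ValueError(
                    f"axis {ax} (size {s}) not divisible by patch size "
                    f"{self.patch_size}"
                )

    def to_dict(self) -> dict:
        return {
            "patch_size": self.patch_size,
            "embed_dim": self.embed_dim,
            "depths": list(self.depths),
            "window": self.window,
            "heads": list(self.heads),
            "use_skip": self.use_skip,
            "encoder": self.encoder,
            "decoder_hidden": self.decoder_hidden,
            "decoder_depth": self.decoder_depth,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetConfig":
        d = dict(d)
        d["depths"] = tuple(d["depths"])
        d["heads"] = tuple(d["heads"])
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Per-stage channels-last feature grids for one modality."""

    stages: list  # list[Tensor], stage s at resolution input/(K·2^s), dim D·2^s
    cfg: NetConfig = dc_field(repr=False, default=None)

    def shapes(self):
        return [t.shape for t in self.stages]


# ----------------------------------------------------------- patch embedding
def patch_tokens(vol: np.ndarray, cfg: NetConfig) -> Tensor:
    """Rearrange a volume into S = HWL/K³ flattened patches (S, K³)."""
    cfg.validate_shape(vol.shape)
    K = cfg.patch_size
    H, W, L = vol.shape
    t = Tensor(np.ascontiguousarray(vol, dtype=np.float32))
    t = ad.reshape(t, (H // K, K, W // K, K, L // K, K))
    t = ad.transpose(t, (0, 2, 4, 1, 3, 5))
    return ad.reshape(t, ((H // K) * (W // K) * (L // K), K**3))


class PatchEmbed(Module):
    def __init__(self, cfg: NetConfig, rng):
        self.cfg = cfg
        self.proj = Linear(cfg.patch_size**3, cfg.embed_dim, rng)

    def forward(self, vol: np.ndarray) -> Tensor:
        K = self.cfg.patch_size
        H, W, L = vol.shape
        tok = self.proj(patch_tokens(vol, self.cfg))
        return ad.reshape(tok, (H // K, W // K, L // K, self.cfg.embed_dim))


def patch_embed(vol, cfg: NetConfig, rng: np.random.Generator | None = None) -> Tensor:
    """Standalone patch embedding: (S, D) token sequence, no positional term."""
    data = vol.data if hasattr(vol, "data") and not isinstance(vol, np.ndarray) else vol
    data = np.asarray(data, dtype=np.float32)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    emb = PatchEmbed(cfg, rng)
    out = emb(data)
    return ad.reshape(out, (-1, cfg.embed_dim))


# ------------------------------------------------------------------- encoder
@lru_cache(maxsize=128)
def _stage_window(shape, window):
    return tuple(min(window, s) for s in shape)


class Encoder(Module):
    """Hierarchical encoder: patch embed, then per stage a run of
    (alternating plain / half-shifted) windowed-attention blocks, with patch
    merging (×½ resolution, ×2 channels) between stages."""

    def __init__(self, cfg: NetConfig, rng):
        self.cfg = cfg
        self.embed = PatchEmbed(cfg, rng)
        self.stages = []
        self.mergings = []
        for s, depth in enumerate(cfg.depths):
            dim = cfg.stage_dim(s)
            if cfg.encoder == "attention":
                blocks = [SwinBlock(dim, cfg.heads[s], rng) for _ in range(depth)]
            else:
                blocks = [ConvStage(dim, depth, rng)]
            self.stages.append(blocks)
            if s < cfg.n_stages - 1:
                self.mergings.append(PatchMerging(dim, rng))

    def forward(self, vol: np.ndarray) -> FeaturePyramid:
        x = self.embed(vol)
        feats = []
        for s, blocks in enumerate(self.stages):
            if self.cfg.encoder == "attention":
                for i, blk in enumerate(blocks):
                    x = self._attn_block(blk, x, shifted=(i % 2 == 1))
            else:
                x = blocks[0](x)
            feats.append(x)
            if s < self.cfg.n_stages - 1:
                x = self.mergings[s](x)
        return FeaturePyramid(stages=feats, cfg=self.cfg)

    def _attn_block(self, blk, x, shifted: bool):
        H, W, L, C = x.shape
        win = _stage_window((H, W, L), self.cfg.window)
        pads = tuple((-d) % w for d, w in zip((H, W, L), win))
        if any(pads):
            x = ad.pad(x, tuple((0, p) for p in pads) + ((0, 0),))
        shifts = tuple(
            (w // 2 if (shifted and d > w and w > 1) else 0)
            for d, w in zip(x.shape[:3], win)
        )
        x = blk(x, win, shifts)
        if any(pads):
            x = x[:H, :W, :L, :]
        return x


# ------------------------------------------------------------------- decoder
def _to_ncdhw(x: Tensor) -> Tensor:
    t = ad.transpose(x, (3, 0, 1, 2))
    return ad.reshape(t, (1,) + t.shape)


class PyramidDecoder(Module):
    """Shared convolutional decoder predicting fields coarse to fine."""

    def __init__(self, cfg: NetConfig, rng):
        self.cfg = cfg
        hid = cfg.decoder_hidden
        self.mix = []
        self.flow = []
        for s in range(cfg.n_stages):
            c_in = 2 * cfg.stage_dim(s)
            if s < cfg.n_stages - 1:
                c_in += 3  # upsampled running field
                if cfg.use_skip:
                    c_in += hid  # upsampled decoder state
            convs = [Conv3d(c_in, hid, 3, rng)]
            convs += [Conv3d(hid, hid, 3, rng)
                      for _ in range(cfg.decoder_depth - 1)]
            self.mix.append(convs)
            self.flow.append(Conv3d(hid, 3, 3, rng, zero_init=True))

    def forward(self, moving: FeaturePyramid, fixed: FeaturePyramid):
        if moving.shapes() != fixed.shapes():
            raise ValueError("pyramid shape mismatch between modalities")
        S = self.cfg.n_stages
        fields = []  # coarse -> fine
        h_prev = None
        field = None
        for s in range(S - 1, -1, -1):
            m = _to_ncdhw(moving.stages[s])
            f = _to_ncdhw(fixed.stages[s])
            grid = m.shape[2:]
            if field is None:
                x = ad.concat([m, f], axis=1)
            else:
                up = ad.resize3(field, grid, scale=2.0)
                m_w = ad.reshape(
                    ad.warp3d(ad.reshape(m, m.shape[1:]), up), m.shape
                )
                parts = [m_w, f, ad.reshape(up, (1, 3) + grid)]
                if self.cfg.use_skip and h_prev is not None:
                    hp = ad.reshape(h_prev, h_prev.shape[1:])
                    parts.append(
                        ad.reshape(ad.resize3(hp, grid, scale=1.0),
                                   (1, h_prev.shape[1]) + grid)
                    )
                x = ad.concat(parts, axis=1)
            h = x
            for conv in self.mix[s]:
                h = ad.leaky_relu(conv(h))
            delta = ad.reshape(self.flow[s](h), (3,) + grid)
            if field is None:
                field = delta
            else:
                # compose: refine-then-accumulate, delta(x + up(x)) + up(x)
                field = ad.warp3d(delta, up) + up
            fields.append(field)
            h_prev = h
        return fields  # [ϕ_coarsest, ..., ϕ_finest]


class SPRNet(Module):
    """Two independent encoders + shared pyramid decoder.

    ``forward`` maps a (moving, fixed) volume pair — numpy grids, already
    normalised — to the predicted displacement field at input resolution,
    along with the per-level decoder fields (coarse → fine).
    """

    def __init__(self, cfg: NetConfig):
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.enc_moving = Encoder(cfg, rng)
        self.enc_fixed = Encoder(cfg, rng)
        self.decoder = PyramidDecoder(cfg, rng)

    def encode(self, vol: np.ndarray, which: str) -> FeaturePyramid:
        if which == "moving":
            return self.enc_moving(np.asarray(vol, dtype=np.float32))
        if which == "fixed":
            return self.enc_fixed(np.asarray(vol, dtype=np.float32))
        raise ValueError(f"which must be moving|fixed, got {which!r}")

    def forward(self, moving: np.ndarray, fixed: np.ndarray):
        moving = np.asarray(moving, dtype=np.float32)
        fixed = np.asarray(fixed, dtype=np.float32)
        if moving.shape != fixed.shape:
            raise ValueError("moving/fixed shape mismatch")
        self.cfg.validate_shape(moving.shape)
        mp = self.enc_moving(moving)
        fp = self.enc_fixed(fixed)
        fields = self.decoder(mp, fp)
        final = ad.resize3(fields[-1], moving.shape,
                           scale=float(self.cfg.patch_size))
        return final, fields
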