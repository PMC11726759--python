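"""Four-stage coarse-to-fine registration cascade.

Stage inputs move from global to local and back: the coarsest stage
(level 3) registers the low-frequency ``aaa`` wavelet approximations, the
two middle stages (levels 2 and 1) register the high-frequency enhancement
images ``E`` (local detail, largely modality-independent), and the final
stage (level 0) registers the original normalised volumes.  Each stage's
network refines the accumulated field, which is carried across stages by
``ϕ_ref ∘ ϕ_acc + ϕ_acc`` composition after upsampling to the stage grid.

Two fidelity choices worth knowing about:

* each stage's moving representation is computed once from the *original*
  moving volume and then warped by the accumulated field (rather than
  re-deriving wavelet inputs from repeatedly warped images), which avoids
  compounding interpolation error and keeps the whole forward pass
  differentiable through the field chain;
* the two E-levels share the same level-1 enhancement image, resampled to
  each stage grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional

import numpy as np

from .defield import DisplacementField, warp
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .sprnet import NetConfig, SPRNet
from .volio import Volume, normalize_intensity, resample_to
from .wavelet3d import dwt3_level, enhance_highfreq

LEVEL_SOURCES = ("aaa", "E", "E", "original")
LEVEL_SCALES = (0.125, 0.25, 0.5, 1.0)


@dataclass
class CascadeConfig:
    sources: tuple[str, ...] = LEVEL_SOURCES
    scales: tuple[float, ...] = LEVEL_SCALES
    wavelet: str = "db5"
    net: NetConfig = dc_field(default_factory=NetConfig)
    share_params: bool = False
    seed: int = 0

    def __post_init__(self):
        if len(self.sources) != 4 or len(self.scales) != 4:
            raise ValueError("cascade has exactly 4 levels")
        if list(self.scales) != sorted(self.scales):
            raise ValueError("levels must be ordered coarse to fine")
        for s in self.sources:
            if s not in ("aaa", "E", "original"):
                raise ValueError(f"unknown stage source {s!r}")

    def stage_shape(self, shape, stage: int) -> tuple[int, int, int]:
        return tuple(max(1, int(round(s * self.scales[stage]))) for s in shape)


def make_nets(cfg: CascadeConfig) -> list[SPRNet]:
    """One SPR-Net per level (independent parameters), or one shared."""
    if cfg.share_params:
        net = SPRNet(replace(cfg.net, seed=cfg.seed))
        return [net] * 4
    return [SPRNet(replace(cfg.net, seed=cfg.seed + 101 * (i + 1)))
            for i in range(4)]


@dataclass
class RegistrationResult:
    field: DisplacementField                    # final, full resolution
    stage_fields: list[DisplacementField]       # accumulated, per stage grid
    stage_refinements: list[DisplacementField]  # per-stage net output
    warped: Volume
    stage_inputs: list[tuple[np.ndarray, np.ndarray]]  # (fixed, moving) grids
    metrics: dict = dc_field(default_factory=dict)


def stage_input(fixed: Volume, moving: Volume, level: int,
                cfg: CascadeConfig) -> tuple[np.ndarray, np.ndarray]:
    """Build the (fixed, moving) representation pair for one level, on the
    stage grid, each min-max normalised to [0, 1].

    ``level`` follows the coarse-to-fine naming: 3 is the coarsest.
    """
    if level not in (0, 1, 2, 3):
        raise ValueError(f"invalid level {level}")
    stage = 3 - level  # position in the configured tuples
    source = cfg.sources[stage]
    out = []
    for vol in (fixed, moving):
        rep = _representation(vol, source, cfg)
        target = cfg.stage_shape(vol.shape, stage)
        if rep.shape != target:
            rep = resample_to(rep, target)
        out.append(normalize_intensity(rep, "minmax").data)
    return out[0], out[1]


def _representation(vol: Volume, source: str, cfg: CascadeConfig) -> Volume:
    if source == "original":
        return vol
    subs = dwt3_level(vol, wavelet=cfg.wavelet, levels=3)
    if source == "aaa":
        return Volume(subs[-1].bands["aaa"], vol.spacing, vol.origin, vol.modality)
    enh = enhance_highfreq(subs[0])
    return Volume(enh.data, vol.spacing, vol.origin, vol.modality)


def forward_cascade(fixed: Volume, moving: Volume, cfg: CascadeConfig,
                    nets: list[SPRNet],
                    stage_cache: Optional[list] = None) -> dict:
    """Differentiable cascade forward pass.

    Returns a dict with per-stage accumulated/refinement field Tensors and
    the stage input grids.  ``stage_cache`` (from :func:`prepare_stages`)
    skips recomputing wavelet inputs when iterating over the same pair.
    """
    if fixed.shape != moving.shape:
        raise ValueError(f"grid mismatch: {fixed.shape} vs {moving.shape}")
    if any(s % 8 for s in fixed.shape):
        raise ValueError("grid must be divisible by 8 (3 dyadic levels)")
    inputs = stage_cache if stage_cache is not None else prepare_stages(
        fixed, moving, cfg
    )
    acc: Tensor | None = None
    accs: list[Tensor] = []
    refinements: list[Tensor] = []
    for stage in range(4):
        f_in, m_in = inputs[stage]
        grid = f_in.shape
        if acc is None:
            m_feed = m_in
            up = None
        else:
            ratios = {t / s for t, s in zip(grid, acc.shape[1:])}
            ratio = ratios.pop()
            if ratios:
                raise ValueError("non-uniform stage grid ratio")
            up = ad.resize3(acc, grid, scale=float(ratio)) if ratio != 1 else acc
            with ad.no_grad():
                m_feed = ad.warp3d(
                    Tensor(m_in[None]), Tensor(up.data)
                ).data[0]
        refinement, _ = nets[stage](m_feed, f_in)
        if up is None:
            acc = refinement
        else:
            acc = ad.warp3d(refinement, up) + up
        refinements.append(refinement)
        accs.append(acc)
    return {"inputs": inputs, "accumulated": accs, "refinements": refinements}


def prepare_stages(fixed: Volume, moving: Volume,
                   cfg: CascadeConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    return [stage_input(fixed, moving, 3 - stage, cfg) for stage in range(4)]


def register(fixed: Volume, moving: Volume, cfg: CascadeConfig,
             nets: list[SPRNet]) -> RegistrationResult:
    """Full four-stage registration of a volume pair (inference)."""
    with ad.no_grad():
        out = forward_cascade(fixed, moving, cfg, nets)
    final = DisplacementField(out["accumulated"][-1].data.astype(np.float64))
    warped = warp(moving, final)
    return RegistrationResult(
        field=final,
        stage_fields=[DisplacementField(t.data.astype(np.float64))
                      for t in out["accumulated"]],
        stage_refinements=[DisplacementField(t.data.astype(np.float64))
                           for t in out["refinements"]],
        warped=warped,
        stage_inputs=out["inputs"],
    )
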