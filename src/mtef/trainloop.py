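"""End-to-end cascade training: loss assembly, learning-rate schedule,
optimisation, logging and checkpointing.

The loss is a similarity term plus diffusion regularisation
(λ · mean squared spatial gradient of the displacement field).  With deep
supervision (the default) the loss is applied at every cascade stage, each
on its own stage representation — the coarse stages therefore receive a
direct training signal instead of waiting for gradients to trickle down
the composition chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import simeval
from .cascade import CascadeConfig, forward_cascade, prepare_stages
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.optim import Adam


@dataclass
class TrainConfig:
    iterations: int = 15000
    base_lr: float = 1e-4
    decay_factor: float = 0.6
    decay_every: int = 1000
    decay_after: int = 5000
    similarity: str = "ncc"          # or "evaluator"
    ncc_window: int | tuple[int, int, int] = 9
    lambda_smooth: float = 1.0
    deep_supervision: bool = True
    #: per-stage loss weights, coarse→fine; the middle (enhancement-image)
    #: stages are the most modality-robust and carry the most weight
    stage_weights: tuple[float, float, float, float] = (0.5, 1.0, 1.0, 0.5)
    #: linear learning-rate warm-up (iterations); 0 disables it
    warmup: int = 0
    #: training pairs whose losses are averaged per iteration
    batch_size: int = 1
    seed: int = 0
    log_every: int = 1
    checkpoint_every: int = 0        # 0 = no checkpoints
    checkpoint_dir: str | None = None

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("learning rate must be > 0")
        if self.lambda_smooth < 0:
            raise ValueError("lambda must be >= 0")
        if self.similarity not in ("ncc", "evaluator"):
            raise ValueError(f"unknown similarity kind {self.similarity!r}")


def lr_schedule(iteration: int, cfg: TrainConfig) -> float:
    """Base rate up to ``decay_after`` iterations, then multiplied by
    ``decay_factor`` once per started ``decay_every`` block."""
    if iteration < 0:
        raise ValueError("iteration must be >= 0")
    if cfg.warmup > 0 and iteration < cfg.warmup:
        return cfg.base_lr * (iteration + 1) / cfg.warmup
    if iteration <= cfg.decay_after:
        return cfg.base_lr
    k = math.ceil((iteration - cfg.decay_after) / cfg.decay_every)
    return cfg.base_lr * cfg.decay_factor**k


def smoothness_penalty(field: Tensor) -> Tensor:
    """Mean squared forward-difference gradient of the field vectors."""
    total = None
    n_axes = 0
    for ax in range(1, 4):
        if field.shape[ax] < 2:
            continue
        sl_hi = [slice(None)] * 4
        sl_lo = [slice(None)] * 4
        sl_hi[ax] = slice(1, None)
        sl_lo[ax] = slice(0, -1)
        d = field[tuple(sl_hi)] - field[tuple(sl_lo)]
        term = ad.reduce_mean(d * d)
        total = term if total is None else total + term
        n_axes += 1
    return total * (1.0 / max(n_axes, 1))


def similarity_term(warped, fixed, cfg: TrainConfig, evaluator=None) -> Tensor:
    if cfg.similarity == "evaluator":
        if evaluator is None:
            raise ValueError("evaluator similarity requested but none given")
        return simeval.similarity(evaluator, warped, fixed)
    return simeval.ncc(warped, fixed, window=cfg.ncc_window)


def loss(warped, fixed, field, cfg: TrainConfig, evaluator=None) -> Tensor:
    """similarity(warped, fixed) + λ · smoothness(field)."""
    sim = similarity_term(warped, fixed, cfg, evaluator)
    if cfg.lambda_smooth == 0:
        return sim
    return sim + cfg.lambda_smooth * smoothness_penalty(ad.as_tensor(field))


def _cascade_loss(out: dict, cfg: TrainConfig, evaluator=None) -> Tensor:
    inputs = out["inputs"]
    accs = out["accumulated"]
    refinements = out["refinements"]
    stages = range(4) if cfg.deep_supervision else [3]
    total = None
    wsum = 0.0
    for s in stages:
        w = cfg.stage_weights[s] if cfg.deep_supervision else 1.0
        if w == 0:
            continue
        f_in, m_in = inputs[s]
        warped = ad.warp3d(Tensor(m_in[None]), accs[s])
        warped = ad.reshape(warped, f_in.shape)
        term = similarity_term(warped, f_in, cfg, evaluator)
        if cfg.lambda_smooth > 0:
            term = term + cfg.lambda_smooth * smoothness_penalty(refinements[s])
        term = term * w
        wsum += w
        total = term if total is None else total + term
    return total * (1.0 / wsum)


def fit(pairs, nets, cfg: TrainConfig, cascade_cfg: CascadeConfig,
        evaluator=None, verbose: bool = False):
    """Train the cascade networks jointly on (fixed, moving) volume pairs.

    Stage inputs are precomputed per pair (the wavelet representations do
    not change during training).  Returns ``(nets, history)`` where
    ``history`` is a DataFrame of per-iteration loss and learning rate.
    Aborts with a diagnostic on NaN loss.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    caches = [prepare_stages(f, m, cascade_cfg) for f, m in pairs]
    params = []
    seen = set()
    for net in nets:
        for p in net.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                params.append(p)
    opt = Adam(params, lr=cfg.base_lr)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for it in range(cfg.iterations):
        opt.lr = lr_schedule(it, cfg)
        k = min(cfg.batch_size, len(pairs))
        idxs = rng.choice(len(pairs), size=k, replace=False)
        opt.zero_grad()
        value = 0.0
        for idx in idxs:
            fixed, moving = pairs[idx]
            out = forward_cascade(fixed, moving, cascade_cfg, nets,
                                  stage_cache=caches[idx])
            total = _cascade_loss(out, cfg, evaluator) * (1.0 / k)
            value += float(total.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: non-finite loss at iteration {it} "
                    f"(pair {idx}, lr {opt.lr:.2e})"
                )
            total.backward()
        opt.step()
        if it % cfg.log_every == 0:
            rows.append({"iteration": it, "lr": opt.lr, "loss": value,
                         "pair": int(idxs[0])})
        if verbose and it % 25 == 0:
            print(f"iter {it:5d} lr {opt.lr:.2e} loss {value:.4f}")
        if cfg.checkpoint_every and (it + 1) % cfg.checkpoint_every == 0:
            _save_checkpoint(nets, cfg, it + 1)
    history = pd.DataFrame(rows)
    return nets, history


def _save_checkpoint(nets, cfg: TrainConfig, iteration: int):
    if cfg.checkpoint_dir is None:
        return
    outdir = Path(cfg.checkpoint_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, net in enumerate(nets):
        np.savez(outdir / f"net{i}_iter{iteration}.npz", **net.state_dict())


def save_nets(nets, outdir: str | Path):
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, net in enumerate(nets):
        np.savez(outdir / f"net{i}.npz", **net.state_dict())


def load_nets(nets, outdir: str | Path):
    outdir = Path(outdir)
    for i, net in enumerate(nets):
        with np.load(outdir / f"net{i}.npz") as data:
            net.load_state_dict({k: data[k] for k in data.files})
    return nets
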