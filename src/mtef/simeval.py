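"""Self-supervised similarity evaluator.

The evaluator learns to score the *spatial* discrepancy between two images
while ignoring appearance (distribution) differences.  Training pairs are
manufactured from a single volume M: two random spatial transforms K1, K2
give M1 and M2; the regression target is the mean absolute intensity of
the difference image M2 − M1 (a pure spatial-error summary); and the
network never sees the clean M1 — it sees M1 corrupted by a dual-structure
morphological transform plus Gaussian noise, which simulates the organ
shape/appearance changes seen across modalities and bladder-filling
states.  A network that solves this task must measure spatial
misalignment through appearance change, which is exactly what a
multimodal registration loss needs.

The trained evaluator is exposed as a differentiable similarity: lower
scores mean better alignment.  A local (windowed) correlation similarity
is provided alongside as the classic baseline; following common practice
for registration losses it uses the *squared* local correlation
coefficient, which also makes it invariant to local linear intensity
flips.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import bimorph
from .nn import autodiff as ad
from .nn.autodiff import Tensor
from .nn.layers import Conv3d, Linear, Module, ResBlock3d
from .volio import Volume

ROTATION_RANGE = (-3.0, 3.0)      # degrees per axis
TRANSLATION_RANGE = (-3.0, 3.0)   # voxels per axis
SCALE_RANGE = (0.92, 1.08)        # isotropic


@dataclass
class TransformSpec:
    rotation_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scale: float = 1.0
    field_amplitude: float = 0.0   # smooth per-voxel deformation, voxels
    field_smoothness: float = 6.0
    field_seed: int = 0

    def __post_init__(self):
        for r in self.rotation_deg:
            if not ROTATION_RANGE[0] <= r <= ROTATION_RANGE[1]:
                raise ValueError("rotation outside configured range")
        for t in self.translation:
            if not TRANSLATION_RANGE[0] <= t <= TRANSLATION_RANGE[1]:
                raise ValueError("translation outside configured range")
        if not SCALE_RANGE[0] <= self.scale <= SCALE_RANGE[1]:
            raise ValueError("scale outside configured range")

    def is_identity(self) -> bool:
        return (all(r == 0 for r in self.rotation_deg)
                and all(t == 0 for t in self.translation)
                and self.scale == 1.0 and self.field_amplitude == 0.0)


def sample_transform(rng: np.random.Generator,
                     field_amplitude: float = 1.0,
                     field_smoothness: float = 6.0,
                     magnitude: float = 1.0) -> TransformSpec:
    """Draw a random transform; deterministic for a given generator state.

    ``magnitude`` in [0, 1] shrinks every drawn parameter towards the
    identity, which is how a dataset with a controlled spread of spatial
    errors is produced.
    """
    if not 0.0 <= magnitude <= 1.0:
        raise ValueError("magnitude must be in [0, 1]")
    s = float(rng.uniform(*SCALE_RANGE))
    return TransformSpec(
        rotation_deg=tuple(magnitude * rng.uniform(*ROTATION_RANGE, size=3)),
        translation=tuple(magnitude * rng.uniform(*TRANSLATION_RANGE, size=3)),
        scale=1.0 + magnitude * (s - 1.0),
        field_amplitude=magnitude * field_amplitude,
        field_smoothness=field_smoothness,
        field_seed=int(rng.integers(0, 2**31 - 1)),
    )


def _rotation_matrix(deg) -> np.ndarray:
    rx, ry, rz = np.deg2rad(deg)
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rx @ Ry @ Rz


def apply_transform(vol: Volume, spec: TransformSpec) -> Volume:
    """Affine (rotate/translate/scale about the centre) followed by an
    optional smooth random per-voxel field; trilinear resampling."""
    if spec.is_identity():
        return vol.with_data(vol.data.copy())
    M = _rotation_matrix(spec.rotation_deg) * spec.scale
    c = (np.asarray(vol.shape) - 1) / 2.0
    offset = c - M @ c + np.asarray(spec.translation)
    data = ndimage.affine_transform(vol.data, M, offset=offset, order=1,
                                    mode="nearest")
    if spec.field_amplitude > 0:
        rng = np.random.default_rng(spec.field_seed)
        u = rng.standard_normal((3, *vol.shape))
        for cax in range(3):
            u[cax] = ndimage.gaussian_filter(u[cax], spec.field_smoothness)
        mag = np.sqrt((u**2).sum(axis=0)).max()
        if mag > 1e-9:
            u *= spec.field_amplitude / mag
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in vol.shape],
                            indexing="ij")
        pts = np.stack([g + u[i] for i, g in enumerate(grids)])
        data = ndimage.map_coordinates(data, pts, order=1, mode="nearest")
    return vol.with_data(data)


@dataclass
class EvaluatorSample:
    """One training example for the evaluator."""

    reference: np.ndarray     # M2
    corrupted: np.ndarray     # dual-morphology(M1) + noise
    target: float             # mean |M2 - M1|, computed from the clean M1
    meta: dict = dc_field(default_factory=dict)


def make_sample(M: Volume, pair: bimorph.StructuringPair | None = None,
                noise_sd: float = 0.05, seed: int = 0,
                field_amplitude: float = 1.0,
                specs: tuple[TransformSpec, TransformSpec] | None = None,
                ) -> EvaluatorSample:
    """Build one evaluator sample from a normalised volume.

    The target uses the clean M1; the corruption (morphology + noise) is
    applied only to the network input, so the target is invariant to it.
    """
    rng = np.random.default_rng(seed)
    if specs is None:
        k1 = sample_transform(rng, field_amplitude=field_amplitude)
        k2 = sample_transform(rng, field_amplitude=field_amplitude)
    else:
        k1, k2 = specs
    if pair is None:
        radius = int(rng.choice(bimorph.DEFAULT_RADII))
        pair = bimorph.preset_pair(radius)
    m1 = apply_transform(M, k1).data
    m2 = apply_transform(M, k2).data
    corrupted = bimorph.dual_close(m1, pair)
    corrupted = corrupted + rng.normal(0.0, noise_sd, size=corrupted.shape)
    target = float(np.abs(m2 - m1).mean())
    return EvaluatorSample(
        reference=m2.astype(np.float32),
        corrupted=corrupted.astype(np.float32),
        target=target,
        meta={"radius": pair.outer, "noise_sd": noise_sd, "seed": seed},
    )


# ------------------------------------------------------------------ network
class Evaluator(Module):
    """Channel-reduced 3D residual regressor of the spatial-error scalar.

    Fully convolutional trunk with two stride-2 reductions and residual
    blocks, global average pooling, and a linear head. Works on any input
    shape with at least 8 voxels per axis.
    """

    def __init__(self, width: int = 8, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.width = width
        self.stem = Conv3d(2, width, 3, rng)
        self.block1 = ResBlock3d(width, rng)
        self.down1 = Conv3d(width, 2 * width, 3, rng, stride=2)
        self.block2 = ResBlock3d(2 * width, rng)
        self.down2 = Conv3d(2 * width, 4 * width, 3, rng, stride=2)
        self.block3 = ResBlock3d(4 * width, rng)
        self.head = Linear(4 * width, 1, rng)
        self.trained = False

    def forward(self, x) -> Tensor:
        """x: (N, 2, H, W, L) Tensor or array -> (N,) predictions."""
        x = ad.as_tensor(x)
        h = ad.relu(self.stem(x))
        h = self.block1(h)
        h = ad.relu(self.down1(h))
        h = self.block2(h)
        h = ad.relu(self.down2(h))
        h = self.block3(h)
        pooled = ad.reduce_mean(h, axis=(2, 3, 4))   # (N, C)
        return ad.reshape(self.head(pooled), (-1,))

    def predict(self, reference: np.ndarray, corrupted: np.ndarray) -> float:
        with ad.no_grad():
            x = np.stack([reference, corrupted])[None].astype(np.float32)
            return max(0.0, float(self.forward(x).data[0]))

    # ---------------------------------------------------------- checkpoints
    def save(self, path: str | Path, meta: dict | None = None):
        path = Path(path)
        np.savez(path.with_suffix(".npz"), **self.state_dict())
        info = {"width": self.width, "trained": self.trained}
        info.update(meta or {})
        path.with_suffix(".json").write_text(json.dumps(info, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "Evaluator":
        path = Path(path)
        info = json.loads(path.with_suffix(".json").read_text())
        ev = cls(width=info["width"])
        with np.load(path.with_suffix(".npz")) as data:
            ev.load_state_dict({k: data[k] for k in data.files})
        ev.trained = info.get("trained", False)
        return ev


def train_evaluator(samples: list[EvaluatorSample], epochs: int = 30,
                    seed: int = 0, lr: float = 1e-3, batch_size: int = 8,
                    width: int = 8, verbose: bool = False) -> Evaluator:
    """L1 regression of the spatial-error target; deterministic under seed."""
    if not samples:
        raise ValueError("empty dataset")
    from .nn.optim import Adam

    ev = Evaluator(width=width, seed=seed)
    opt = Adam(ev.parameters(), lr=lr)
    rng = np.random.default_rng(seed + 1)
    X = np.stack([np.stack([s.reference, s.corrupted]) for s in samples])
    y = np.array([s.target for s in samples], dtype=np.float32)
    n = len(samples)
    for epoch in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            pred = ev.forward(X[idx])
            loss = ad.reduce_mean(ad.absolute(pred - Tensor(y[idx])))
            opt.zero_grad()
            loss.backward()
            opt.step()
        if verbose:
            with ad.no_grad():
                full = float(np.abs(ev.forward(X).data - y).mean())
            print(f"epoch {epoch}: MAE {full:.4f}")
    ev.trained = True
    return ev


# -------------------------------------------------------------- similarities
def similarity(evaluator: Evaluator, warped, fixed) -> Tensor:
    """Evaluator-predicted spatial error (lower = better aligned);
    differentiable with respect to ``warped``."""
    w = ad.as_tensor(warped.data if isinstance(warped, Volume) else warped)
    f = ad.as_tensor(fixed.data if isinstance(fixed, Volume) else fixed)
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {f.shape}")
    x = ad.stack([f, w])           # reference first, as in training
    x = ad.reshape(x, (1, 2) + w.shape)
    return ad.reshape(evaluator.forward(x), ())


def ncc(warped, fixed, window: int = 9, delta: float = 1e-8) -> Tensor:
    """1 − mean regularised local squared correlation coefficient,
    cc² = (cov² + δ²) / ((var_w + δ)(var_f + δ)).

    Statistics are taken over fully-valid cubic windows only (no padding).
    The score is ~0 for identical inputs and for inputs related by a
    local affine intensity map (cov² = var_w·var_f) — the property that
    lets squared correlation serve as a crude multimodal baseline.  The
    regularisation is deliberately *per-variance*: a window pair that is
    flat on both sides scores as aligned (δ²/δ² = 1), but flattening only
    one side against a textured window scores ≈ δ/var ≈ 0 — a symmetric
    form (δ added to the products) would make "warp everything to a
    constant" a global optimum of the loss.  cc² ≤ 1 always, so the loss
    is non-negative.
    """
    w = ad.as_tensor(warped.data if isinstance(warped, Volume) else warped)
    f = ad.as_tensor(fixed.data if isinstance(fixed, Volume) else fixed)
    if w.shape != f.shape:
        raise ValueError(f"shape mismatch: {w.shape} vs {f.shape}")
    req = (window,) * 3 if np.isscalar(window) else tuple(window)

    def axis_k(n, kr):
        k = min(kr, n)
        if k % 2 == 0:
            k -= 1
        return max(k, 1)

    ks = tuple(axis_k(n, kr) for n, kr in zip(w.shape, req))

    def local_mean(t):
        return ad.box_filter_valid(t, ks)

    mw, mf = local_mean(w), local_mean(f)
    mww, mff = local_mean(w * w), local_mean(f * f)
    mwf = local_mean(w * f)
    cross = mwf - mw * mf
    var_w = mww - mw * mw
    var_f = mff - mf * mf
    cc2 = (cross * cross + delta * delta) / ((var_w + delta) * (var_f + delta))
    return 1.0 - ad.reduce_mean(cc2)
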