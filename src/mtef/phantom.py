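"""Synthetic multimodal pelvic phantoms with known ground-truth deformation.

Each phantom is a labelled "anatomy" of nested ellipsoids — a body outline
containing bladder-, tumour- (CTV), femur- and intestine-like structures —
rendered twice with *different* per-tissue intensity tables to mimic a
CT/MR pair: bone is the brightest tissue in the pseudo-CT but among the
darkest in the pseudo-MR, while fluid (bladder) is dark in CT and bright in
MR.  The contrast orderings are deliberately rank-different so that
mono-modal similarity measures (SSD and friends) are misled while
structure-based registration still has signal.

The moving volume is produced by warping the pseudo-MR rendering with a
known smooth random displacement field, optionally augmented with a radial
organ-expansion component centred on the bladder (emulating filling-state
change).  The generative field ``u*`` is returned; note that the field a
registration should *recover* is approximately the inverse of ``u*``
(exactly ``-u*`` for small smooth deformations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .defield import DisplacementField, warp
from .volio import LabelMap, Volume, write_labelmap, write_volume

TISSUES = {0: "background", 1: "body", 2: "bladder", 3: "ctv",
           4: "femur", 5: "intestine"}

# tissue -> (mean, sd); rank orderings intentionally differ across modalities
CT_TABLE = {0: (0.02, 0.01), 1: (0.35, 0.02), 2: (0.18, 0.02),
            3: (0.45, 0.02), 4: (0.95, 0.02), 5: (0.28, 0.02)}
MR_TABLE = {0: (0.02, 0.01), 1: (0.50, 0.02), 2: (0.92, 0.02),
            3: (0.70, 0.02), 4: (0.12, 0.02), 5: (0.62, 0.02)}


@dataclass
class PhantomSpec:
    shape: tuple[int, int, int] = (64, 64, 16)
    amplitude: float = 10.0         # max random-field displacement, voxels (in-plane)
    smoothness: float = 8.0         # Gaussian sigma of the random field, voxels
    organ_amplitude: float = 4.0    # bladder-centred radial expansion, voxels
    noise_sd: float = 0.02          # rendering noise on top of per-tissue sd
    spacing: tuple[float, float, float] = (1.0, 1.0, 5.0)
    jitter: float = 0.05            # relative geometry jitter per phantom
    seed: int = 0

    def __post_init__(self):
        if self.amplitude < 0 or self.organ_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in shape],
                        indexing="ij")
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return q <= 1.0


def _check_bounds(shape, center, radii, name):
    for s, c, r in zip(shape, center, radii):
        if c - r < -1 or c + r > s:
            raise ValueError(f"organ {name!r} overflows the grid")


def build_tissue_map(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Labelled anatomy on the fixed grid (ids per :data:`TISSUES`)."""
    H, W, L = spec.shape
    j = spec.jitter

    def jit(v):
        return v * (1.0 + rng.uniform(-j, j))

    lab = np.zeros(spec.shape, dtype=np.int32)
    body_c = (H / 2, W / 2, L / 2)
    body_r = (jit(0.44 * H), jit(0.42 * W), jit(0.46 * L))
    _check_bounds(spec.shape, body_c, body_r, "body")
    lab[_ellipsoid(spec.shape, body_c, body_r)] = 1

    organs = {
        2: ((jit(0.42 * H), jit(0.50 * W), jit(0.50 * L)),
            (jit(0.14 * H), jit(0.13 * W), jit(0.22 * L))),   # bladder
        3: ((jit(0.60 * H), jit(0.50 * W), jit(0.50 * L)),
            (jit(0.10 * H), jit(0.10 * W), jit(0.18 * L))),   # CTV
        5: ((jit(0.30 * H), jit(0.30 * W), jit(0.45 * L)),
            (jit(0.09 * H), jit(0.14 * W), jit(0.20 * L))),   # intestine
    }
    for lid, (c, r) in organs.items():
        _check_bounds(spec.shape, c, r, TISSUES[lid])
        lab[_ellipsoid(spec.shape, c, r)] = lid
    # two femoral heads, one label
    for side in (0.18, 0.82):
        c = (jit(0.52 * H), side * W, jit(0.50 * L))
        r = (jit(0.08 * H), jit(0.07 * W), jit(0.16 * L))
        _check_bounds(spec.shape, c, r, "femur")
        lab[_ellipsoid(spec.shape, c, r)] = 4
    return lab


def render(tissue: np.ndarray, table: dict, rng: np.random.Generator,
           noise_sd: float) -> np.ndarray:
    out = np.zeros(tissue.shape, dtype=np.float64)
    for lid, (mu, sd) in table.items():
        m = tissue == lid
        out[m] = mu + rng.normal(0.0, sd, size=int(m.sum()))
    out = ndimage.gaussian_filter(out, 0.7)
    out += rng.normal(0.0, noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def random_smooth_field(spec: PhantomSpec, rng: np.random.Generator,
                        bladder_center=None) -> DisplacementField:
    """Smoothed Gaussian random field scaled to ``amplitude``, plus an
    optional radial expansion around the bladder centre.  The out-of-plane
    component is scaled by the grid aspect so thin stacks are not torn."""
    H, W, L = spec.shape
    u = rng.standard_normal((3, H, W, L))
    for c in range(3):
        u[c] = ndimage.gaussian_filter(u[c], spec.smoothness)
    mag = np.sqrt((u**2).sum(axis=0)).max()
    if mag > 1e-9 and spec.amplitude > 0:
        u *= spec.amplitude / mag
    else:
        u[:] = 0.0
    u[2] *= L / H  # respect grid anisotropy
    if spec.organ_amplitude > 0 and bladder_center is not None:
        grids = np.meshgrid(*[np.arange(s, dtype=np.float64) for s in spec.shape],
                            indexing="ij")
        d = [g - c for g, c in zip(grids, bladder_center)]
        d[2] = d[2] * (H / L)  # isotropise before measuring radius
        r = np.sqrt(sum(x * x for x in d)) + 1e-9
        rho = 0.18 * H
        gain = spec.organ_amplitude * np.exp(-((r / rho) ** 2))
        for c in range(3):
            u[c] += gain * d[c] / r * (1.0 if c < 2 else L / H)
    return DisplacementField(u)


def generate_pair(spec: PhantomSpec):
    """Return ``(fixed, moving, fixed_labels, moving_labels, true_field)``.

    ``fixed`` is the pseudo-CT of the anatomy; ``moving`` is the pseudo-MR
    warped by the returned generative field (plus independent rendering
    noise). Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = build_tissue_map(spec, rng)
    fixed = Volume(render(tissue, CT_TABLE, rng, spec.noise_sd),
                   spec.spacing, modality="pseudo-CT")
    mr = Volume(render(tissue, MR_TABLE, rng, spec.noise_sd),
                spec.spacing, modality="pseudo-MR")
    fixed_labels = LabelMap(tissue.copy(), spec.spacing, dict(TISSUES))

    bl = np.argwhere(tissue == 2)
    bladder_center = bl.mean(axis=0) if len(bl) else None
    true_field = random_smooth_field(spec, rng, bladder_center)
    if spec.amplitude == 0 and spec.organ_amplitude == 0:
        moving = mr
        moving_labels = LabelMap(tissue.copy(), spec.spacing, dict(TISSUES))
    else:
        moving = warp(mr, true_field)
        moving_labels = warp(fixed_labels, true_field)
    return fixed, moving, fixed_labels, moving_labels, true_field


def intensity_rank_differs() -> bool:
    """True when the two modality tables order the tissues differently."""
    ids = sorted(TISSUES)
    ct = np.argsort([CT_TABLE[i][0] for i in ids])
    mr = np.argsort([MR_TABLE[i][0] for i in ids])
    return not np.array_equal(ct, mr)


def benchmark_suite(n: int, spec: PhantomSpec, seed: int,
                    outdir: str | Path) -> dict:
    """Write ``n`` phantom pairs as NIfTI plus a JSON manifest with a
    deterministic 80/20 train/test split."""
    if n < 2:
        raise ValueError("need at least 2 pairs")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    case_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]
    n_train = int(round(0.8 * n))
    entries = []
    for i, cs in enumerate(case_seeds):
        cspec = replace(spec, seed=cs)
        fixed, moving, flab, mlab, fld = generate_pair(cspec)
        stem = outdir / f"case{i:03d}"
        write_volume(fixed, f"{stem}_fixed.nii.gz")
        write_volume(moving, f"{stem}_moving.nii.gz")
        write_labelmap(flab, f"{stem}_fixed_labels.nii.gz")
        write_labelmap(mlab, f"{stem}_moving_labels.nii.gz")
        entries.append({
            "case": i,
            "seed": cs,
            "split": "train" if i < n_train else "test",
            "files": {k: f"case{i:03d}_{k}.nii.gz"
                      for k in ("fixed", "moving", "fixed_labels", "moving_labels")},
        })
    manifest = {
        "n": n,
        "seed": seed,
        "spec": {
            "shape": list(spec.shape),
            "amplitude": spec.amplitude,
            "smoothness": spec.smoothness,
            "organ_amplitude": spec.organ_amplitude,
            "noise_sd": spec.noise_sd,
            "spacing": list(spec.spacing),
            "jitter": spec.jitter,
        },
        "cases": entries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
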