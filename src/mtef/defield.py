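"""Dense displacement-field algebra: warping, composition, resolution
changes and Jacobian-determinant analysis.

A displacement field ϕ stores one 3-vector per voxel, in voxel units of its
own grid, and defines the backward map ``out(x) = in(x + ϕ(x))``.  The same
trilinear sampler used by the differentiable network ops backs the numpy
API here, so a field behaves identically at training and at inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

from .nn.autodiff import _gather_trilinear, _sample_setup
from .volio import LabelMap, Volume


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors, shape (3, H, W, L), voxel units."""

    vectors: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[0] != 3:
            raise ValueError(
                f"expected (3, H, W, L) vectors, got {self.vectors.shape}"
            )
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("field must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[1:]

    @classmethod
    def zeros(cls, shape) -> "DisplacementField":
        return cls(np.zeros((3, *shape)))


def _sample_trilinear(data: np.ndarray, field: np.ndarray) -> np.ndarray:
    setup, _ = _sample_setup(field.astype(np.float64), data.shape)
    return _gather_trilinear(data[None], setup)[0]


def _sample_nearest(data: np.ndarray, field: np.ndarray) -> np.ndarray:
    H, W, L = data.shape
    gx, gy, gz = np.meshgrid(
        np.arange(H), np.arange(W), np.arange(L), indexing="ij"
    )
    px = np.clip(np.rint(gx + field[0]).astype(np.int64), 0, H - 1)
    py = np.clip(np.rint(gy + field[1]).astype(np.int64), 0, W - 1)
    pz = np.clip(np.rint(gz + field[2]).astype(np.int64), 0, L - 1)
    return data[px, py, pz]


def warp(vol: Volume | LabelMap, field: DisplacementField,
         interp: str = "trilinear"):
    """Warp a volume (trilinear or nearest) or label map (always nearest).

    ``out(x) = in(x + ϕ(x))`` with border-clamped out-of-bounds sampling.
    """
    if vol.shape != field.grid_shape:
        raise ValueError(f"shape mismatch: {vol.shape} vs {field.grid_shape}")
    if isinstance(vol, LabelMap):
        data = _sample_nearest(vol.data.astype(np.float64), field.vectors)
        return LabelMap(np.rint(data).astype(vol.data.dtype), vol.spacing,
                        dict(vol.labels))
    if interp == "trilinear":
        data = _sample_trilinear(vol.data, field.vectors)
    elif interp == "nearest":
        data = _sample_nearest(vol.data, field.vectors)
    else:
        raise ValueError(f"unknown interpolation {interp!r}")
    return vol.with_data(data)


def compose(outer: DisplacementField, inner: DisplacementField) -> DisplacementField:
    """Apply ``inner`` first, then ``outer``:
    ``result(x) = outer(x + inner(x)) + inner(x)``.

    Warping with the result equals warping with ``inner`` followed by
    ``outer`` (up to interpolation error).
    """
    if outer.grid_shape != inner.grid_shape:
        raise ValueError(
            f"grid mismatch: {outer.grid_shape} vs {inner.grid_shape}"
        )
    warped_outer = np.stack(
        [_sample_trilinear(outer.vectors[c], inner.vectors) for c in range(3)]
    )
    return DisplacementField(warped_outer + inner.vectors)


def resize_field(field: DisplacementField, target_shape) -> DisplacementField:
    """Trilinearly resample field vectors to a new grid and rescale each
    component by the per-axis grid ratio (voxel-unit change of basis)."""
    src = field.grid_shape
    target_shape = tuple(int(s) for s in target_shape)
    coords = np.meshgrid(
        *[
            np.linspace(0.0, s - 1.0, t) if t > 1 else np.zeros(1)
            for s, t in zip(src, target_shape)
        ],
        indexing="ij",
    )
    from scipy import ndimage

    pts = np.stack(coords)
    out = np.empty((3, *target_shape))
    for c in range(3):
        scale = (target_shape[c] - 1) / max(src[c] - 1, 1) if target_shape[c] > 1 \
            else target_shape[c] / src[c]
        out[c] = ndimage.map_coordinates(
            field.vectors[c], pts, order=1, mode="nearest"
        ) * scale
    return DisplacementField(out)


def upsample_field(field: DisplacementField, factor: int) -> DisplacementField:
    """Upsample to a grid ``factor×`` finer; vector magnitudes scale by
    ``factor`` since displacements are stored in voxel units."""
    if factor < 2:
        raise ValueError("factor must be >= 2")
    src = field.grid_shape
    target = tuple(s * factor for s in src)
    coords = np.meshgrid(
        *[np.linspace(0.0, s - 1.0, t) for s, t in zip(src, target)],
        indexing="ij",
    )
    from scipy import ndimage

    pts = np.stack(coords)
    out = np.stack(
        [
            ndimage.map_coordinates(field.vectors[c], pts, order=1, mode="nearest")
            for c in range(3)
        ]
    )
    return DisplacementField(out * factor)


def jacobian_determinant(field: DisplacementField) -> np.ndarray:
    """Determinant of ∂(x + ϕ(x))/∂x at interior voxels (central
    differences). Returns an (H−2, W−2, L−2) map."""
    if any(s < 3 for s in field.grid_shape):
        raise ValueError("grid must be >= 3 per axis for interior Jacobians")
    u = field.vectors
    J = np.empty((3, 3, *field.grid_shape))
    for c in range(3):
        gx, gy, gz = np.gradient(u[c])
        J[c, 0], J[c, 1], J[c, 2] = gx, gy, gz
    for c in range(3):
        J[c, c] += 1.0
    interior = (slice(1, -1),) * 3
    Ji = J[(slice(None), slice(None)) + interior]
    Ji = np.moveaxis(Ji, (0, 1), (-2, -1))
    return np.linalg.det(Ji)


def jacobian_nonpositive_fraction(field: DisplacementField):
    """Fraction (in [0, 1]) of interior voxels with Jacobian determinant
    ≤ 0 (folding), plus the determinant map."""
    det = jacobian_determinant(field)
    return float((det <= 0).mean()), det


# ------------------------------------------------------------------- NIfTI
def write_field(field: DisplacementField, path: str | Path,
                spacing=(1.0, 1.0, 1.0)):
    """Save as 4D NIfTI, last axis = vector component in (x, y, z) order."""
    arr = np.moveaxis(field.vectors, 0, -1).astype(np.float32)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_field(path: str | Path) -> DisplacementField:
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(f"expected (H, W, L, 3) field file, got {arr.shape}")
    return DisplacementField(np.moveaxis(arr, -1, 0))
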