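"""Volume and label-map containers with NIfTI I/O, resampling and
intensity normalisation.

Conventions used throughout the package: 0-based voxel indices, axis order
``(x, y, z)`` mapped to array axes ``(H, W, L)``; physical spacing (mm) is
carried on the container but all displacement-field arithmetic is done in
voxel units of the grid it lives on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage


@dataclass
class Volume:
    """A 3D scalar image: data grid + mm spacing + mm origin + modality tag."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D volume, got {self.data.ndim}D")
        if any(s < 1 for s in self.data.shape):
            raise ValueError("all dimensions must be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=data)


@dataclass
class LabelMap:
    """Integer label grid aligned with a :class:`Volume`. 0 = background."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D label map, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("label ids must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.data) if v != 0]


# ------------------------------------------------------------------- NIfTI IO
def read_volume(path: str | Path, modality: str = "") -> Volume:
    """Read a NIfTI-1 volume; casts to floating point."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return Volume(data.astype(np.float64), tuple(float(z) for z in zooms),
                  origin, modality)


def write_volume(vol: Volume, path: str | Path):
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), affine), str(path))


def read_labelmap(path: str | Path) -> LabelMap:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected 3D label map, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    return LabelMap(np.rint(data).astype(np.int32),
                    tuple(float(z) for z in zooms))


def write_labelmap(lab: LabelMap, path: str | Path):
    affine = np.diag(list(lab.spacing) + [1.0])
    nib.save(nib.Nifti1Image(lab.data.astype(np.int16), affine), str(path))


# --------------------------------------------------------------- resampling
def _resample_grid(data: np.ndarray, target_shape, order: int) -> np.ndarray:
    """Endpoint-preserving (align-corners) resampling onto target_shape."""
    src = data.shape
    coords = np.meshgrid(
        *[
            np.linspace(0.0, s - 1.0, t) if t > 1 else np.zeros(1)
            for s, t in zip(src, target_shape)
        ],
        indexing="ij",
    )
    return ndimage.map_coordinates(
        data.astype(np.float64), np.stack(coords), order=order, mode="nearest"
    )


def resample_to(vol: Volume, target_shape, target_spacing=None) -> Volume:
    """Trilinear resample onto a grid of ``target_shape``."""
    target_shape = tuple(int(s) for s in target_shape)
    if any(s < 1 for s in target_shape):
        raise ValueError("target_shape must be >= 1 per axis")
    if target_shape == vol.shape:
        data = vol.data.copy()
    else:
        data = _resample_grid(vol.data, target_shape, order=1)
    if target_spacing is None:
        target_spacing = tuple(
            sp * (s - 1) / max(t - 1, 1)
            for sp, s, t in zip(vol.spacing, vol.shape, target_shape)
        )
    return Volume(data, tuple(float(s) for s in target_spacing), vol.origin,
                  vol.modality)


def resample_labelmap_to(lab: LabelMap, target_shape) -> LabelMap:
    target_shape = tuple(int(s) for s in target_shape)
    if target_shape == lab.shape:
        return LabelMap(lab.data.copy(), lab.spacing, dict(lab.labels))
    data = _resample_grid(lab.data.astype(np.float64), target_shape, order=0)
    return LabelMap(np.rint(data).astype(np.int32), lab.spacing, dict(lab.labels))


# ------------------------------------------------------------- normalisation
def normalize_intensity(vol: Volume, mode: str = "minmax") -> Volume:
    """Min-max to [0, 1] or z-score to mean 0 / sd 1."""
    data = vol.data
    if mode == "minmax":
        lo, hi = float(data.min()), float(data.max())
        if hi - lo < 1e-12:
            warnings.warn("constant image under minmax normalisation; returning zeros")
            return vol.with_data(np.zeros_like(data))
        return vol.with_data((data - lo) / (hi - lo))
    if mode == "zscore":
        sd = float(data.std())
        if sd < 1e-12:
            warnings.warn("constant image under zscore normalisation; returning zeros")
            return vol.with_data(np.zeros_like(data))
        return vol.with_data((data - data.mean()) / sd)
    raise ValueError(f"unknown normalisation mode {mode!r}")


# ---------------------------------------------------------- background crop
def crop_background(vol: Volume, threshold: float):
    """Crop to the tightest bounding box of voxels above ``threshold``,
    padded out to even side lengths (so dyadic wavelet levels stay exact).

    Returns ``(cropped, offsets)`` where ``offsets`` are the lower corner
    indices of the crop in the original grid (allowing re-embedding).
    """
    mask = vol.data > threshold
    if not mask.any():
        warnings.warn("empty foreground; returning input unchanged")
        return vol, (0, 0, 0)
    if mask.all():
        return vol, (0, 0, 0)
    lo, hi = [], []
    for ax in range(3):
        other = tuple(a for a in range(3) if a != ax)
        prof = mask.any(axis=other)
        idx = np.nonzero(prof)[0]
        lo.append(int(idx[0]))
        hi.append(int(idx[-1]) + 1)
    # pad to even extent, preferring to stay inside the original grid
    for ax in range(3):
        if (hi[ax] - lo[ax]) % 2 == 1:
            if hi[ax] < vol.shape[ax]:
                hi[ax] += 1
            elif lo[ax] > 0:
                lo[ax] -= 1
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    data = vol.data[sl]
    pads = [(0, (b - a) % 2) for a, b in zip(lo, hi)]
    if any(p[1] for p in pads):  # odd full-extent axis: replicate-pad outward
        data = np.pad(data, pads, mode="edge")
    return vol.with_data(data), tuple(lo)


def embed_crop(cropped: Volume, offsets, original_shape) -> Volume:
    """Re-embed a crop into a zero volume of the original shape."""
    out = np.zeros(original_shape)
    sl = tuple(
        slice(o, min(o + s, n)) for o, s, n in zip(offsets, cropped.shape, original_shape)
    )
    out[sl] = cropped.data[tuple(slice(0, s.stop - s.start) for s in sl)]
    return Volume(out, cropped.spacing, cropped.origin, cropped.modality)
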