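"""Grey-scale morphology with dual (ring) structuring elements.

A dual structure is defined by two concentric balls: the outer radius Ra
and inner radius Rb carve out a hollow ring ΔR = ball(Ra) − ball(Rb), and a
third ball Rc of intermediate radius closes the pair.  The dual opening
dilates by the ring and erodes by Rc; the dual closing does the opposite.
The associated white/black top-hats isolate structures narrower than the
ring and are used to simulate large, shape-distorting organ deformation
when building training data for the similarity evaluator.

These are order-statistic (min/max) filters, so they are invariant to
adding a constant and never overshoot the input's range.  Unlike ordinary
openings, ring-element openings are *not* idempotent; no such property is
assumed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

DEFAULT_RADII = (3, 5, 6, 7, 9)


def ball_element(radius: int, ndim: int = 3) -> np.ndarray:
    """Binary ball: voxels with Euclidean distance ≤ radius from the center
    of a (2r+1)^ndim support."""
    radius = int(radius)
    if radius < 1:
        raise ValueError("radius must be >= 1")
    grids = np.meshgrid(*([np.arange(-radius, radius + 1)] * ndim), indexing="ij")
    dist2 = sum(g * g for g in grids)
    return dist2 <= radius * radius


@dataclass(frozen=True)
class StructuringPair:
    """Outer/inner ball radii defining a ring element plus the intermediate
    ball Rc (radius = rounded midpoint, the closest realizable 'intermediate
    size')."""

    outer: int
    inner: int
    slicewise: bool = False  # apply per 2D slice instead of volumetrically

    def __post_init__(self):
        if not (self.outer > self.inner >= 1):
            raise ValueError("require outer > inner >= 1")

    @property
    def rc(self) -> int:
        return int(round((self.outer + self.inner) / 2))

    @property
    def ring_width(self) -> int:
        return self.outer - self.inner

    def _ndim(self) -> int:
        return 2 if self.slicewise else 3

    def ring_element(self) -> np.ndarray:
        """Hollow shell: ball(outer) minus ball(inner)."""
        n = self._ndim()
        outer = ball_element(self.outer, n)
        inner = ball_element(self.inner, n)
        pad = self.outer - self.inner
        inner_p = np.pad(inner, pad)
        ring = outer & ~inner_p
        if not ring.any():
            raise ValueError("degenerate ring element")
        return ring

    def rc_element(self) -> np.ndarray:
        return ball_element(self.rc, self._ndim())


def preset_pair(radius: int, slicewise: bool = False) -> StructuringPair:
    """Deformation-simulation preset named by its outer radius."""
    if radius not in DEFAULT_RADII:
        raise ValueError(f"no preset for radius {radius}; presets: {DEFAULT_RADII}")
    return StructuringPair(outer=radius, inner=max(1, radius - 2),
                           slicewise=slicewise)


def _apply(f: np.ndarray, elem: np.ndarray, op, slicewise: bool) -> np.ndarray:
    f = np.asarray(f, dtype=np.float64)
    if slicewise:
        if f.ndim != 3:
            raise ValueError("slicewise mode expects a 3D volume")
        return np.stack([op(f[..., k], footprint=elem, mode="nearest")
                         for k in range(f.shape[-1])], axis=-1)
    return op(f, footprint=elem, mode="nearest")


def erode(f: np.ndarray, elem: np.ndarray, slicewise: bool = False) -> np.ndarray:
    """Grey-scale erosion (min filter) with replicate border handling."""
    if not np.asarray(elem).any():
        raise ValueError("empty structuring element")
    return _apply(f, elem, ndimage.grey_erosion, slicewise)


def dilate(f: np.ndarray, elem: np.ndarray, slicewise: bool = False) -> np.ndarray:
    """Grey-scale dilation (max filter) with replicate border handling."""
    if not np.asarray(elem).any():
        raise ValueError("empty structuring element")
    return _apply(f, elem, ndimage.grey_dilation, slicewise)


def dual_open(f: np.ndarray, pair: StructuringPair) -> np.ndarray:
    """Opening-like dual operator: erode(dilate(f, ring), ball(Rc))."""
    d = dilate(f, pair.ring_element(), pair.slicewise)
    return erode(d, pair.rc_element(), pair.slicewise)


def dual_close(f: np.ndarray, pair: StructuringPair) -> np.ndarray:
    """Closing-like dual operator: dilate(erode(f, ring), ball(Rc))."""
    e = erode(f, pair.ring_element(), pair.slicewise)
    return dilate(e, pair.rc_element(), pair.slicewise)


def white_tophat_dual(f: np.ndarray, pair: StructuringPair) -> np.ndarray:
    """WTH' = f − dual_open(f): bright structures narrower than the ring."""
    return np.asarray(f, dtype=np.float64) - dual_open(f, pair)


def black_tophat_dual(f: np.ndarray, pair: StructuringPair) -> np.ndarray:
    """BTH' = dual_close(f) − f: dark structures narrower than the ring."""
    return dual_close(f, pair) - np.asarray(f, dtype=np.float64)
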