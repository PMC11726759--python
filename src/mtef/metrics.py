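"""Registration quality metrics: Dice similarity coefficient (DSC),
average symmetric surface distance (ASSD) and the fraction of folded
voxels (Jacobian determinant ≤ 0)."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .defield import DisplacementField, jacobian_nonpositive_fraction, warp
from .volio import LabelMap


def dsc(a: LabelMap, b: LabelMap, label: int) -> float:
    """2|A∩B| / (|A|+|B|) for one label; two empty masks count as 1."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a.data == label
    mb = b.data == label
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels: in the mask with at least one 6-neighbour outside."""
    padded = np.pad(mask, 1, constant_values=False)
    interior = np.ones_like(mask)
    for ax in range(3):
        lo = [slice(1, -1)] * 3
        hi = [slice(1, -1)] * 3
        lo[ax] = slice(0, -2)
        hi[ax] = slice(2, None)
        interior &= padded[tuple(lo)] & padded[tuple(hi)]
    return np.argwhere(mask & ~interior)


def assd(a: LabelMap, b: LabelMap, label: int,
         spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric mean of nearest-surface distances (mm via ``spacing``)."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    ma = a.data == label
    mb = b.data == label
    if not ma.any():
        raise ValueError(f"label {label} empty in first map")
    if not mb.any():
        raise ValueError(f"label {label} empty in second map")
    sa = _surface_voxels(ma) * np.asarray(spacing)
    sb = _surface_voxels(mb) * np.asarray(spacing)
    da = cKDTree(sb).query(sa)[0]
    db = cKDTree(sa).query(sb)[0]
    return float((da.sum() + db.sum()) / (len(da) + len(db)))


@dataclass
class MetricsReport:
    """Per-label overlap/distance metrics plus field-quality summary."""

    dsc_per_label: dict[int, float]
    assd_per_label: dict[int, float]
    jd_nonpositive_percent: float
    pre_dsc_per_label: dict[int, float] = field(default_factory=dict)
    missing_labels: list[int] = field(default_factory=list)

    @property
    def mean_dsc(self) -> float:
        return float(np.mean(list(self.dsc_per_label.values())))

    def to_json(self) -> str:
        return json.dumps(
            {
                "dsc": {str(k): v for k, v in self.dsc_per_label.items()},
                "assd": {str(k): v for k, v in self.assd_per_label.items()},
                "jd_nonpositive_percent": self.jd_nonpositive_percent,
                "pre_dsc": {str(k): v for k, v in self.pre_dsc_per_label.items()},
                "missing_labels": self.missing_labels,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        d = json.loads(s)
        return cls(
            dsc_per_label={int(k): v for k, v in d["dsc"].items()},
            assd_per_label={int(k): v for k, v in d["assd"].items()},
            jd_nonpositive_percent=d["jd_nonpositive_percent"],
            pre_dsc_per_label={int(k): v for k, v in d.get("pre_dsc", {}).items()},
            missing_labels=list(d.get("missing_labels", [])),
        )


def report(fixed_labels: LabelMap, moving_labels: LabelMap,
           fld: DisplacementField, spacing=(1.0, 1.0, 1.0)) -> MetricsReport:
    """Warp the moving labels (nearest neighbour) and assemble per-label DSC
    and ASSD, the pre-registration DSC, and the JD≤0 percentage.

    Labels present in only one map are reported in ``missing_labels``
    rather than silently dropped.
    """
    warped = warp(moving_labels, fld)
    ids_f = set(fixed_labels.ids())
    ids_m = set(moving_labels.ids())
    common = sorted(ids_f & ids_m)
    missing = sorted(ids_f ^ ids_m)
    dscs, assds, pre = {}, {}, {}
    for k in common:
        dscs[k] = dsc(fixed_labels, warped, k)
        pre[k] = dsc(fixed_labels, moving_labels, k)
        if (warped.data == k).any():
            assds[k] = assd(fixed_labels, warped, k, spacing)
        else:  # label collapsed away under warping
            missing.append(k)
    frac, _ = jacobian_nonpositive_fraction(fld)
    return MetricsReport(
        dsc_per_label=dscs,
        assd_per_label=assds,
        jd_nonpositive_percent=100.0 * frac,
        pre_dsc_per_label=pre,
        missing_labels=sorted(missing),
    )
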