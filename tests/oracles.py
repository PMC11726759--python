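"""Independent brute-force oracles shared by the test modules.

Everything here is deliberately naive — per-voxel scans and all-pairs
distances — so it cannot share a failure mode with the implementations it
checks.
"""

import numpy as np
from scipy.spatial.distance import cdist


def brute_filter(f, elem, reducer):
    """Per-voxel min/max scan with replicate borders."""
    f = np.asarray(f, dtype=float)
    r = elem.shape[0] // 2
    offsets = np.argwhere(elem) - r
    out = np.empty_like(f)
    shape = np.array(f.shape)
    for idx in np.ndindex(f.shape):
        pos = np.clip(np.array(idx) + offsets, 0, shape - 1)
        out[idx] = reducer(f[pos[:, 0], pos[:, 1], pos[:, 2]])
    return out


def brute_erode(f, elem):
    return brute_filter(f, elem, np.min)


def brute_dilate(f, elem):
    return brute_filter(f, elem, np.max)


def brute_dsc(ma, mb):
    na, nb = int(ma.sum()), int(mb.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((ma & mb).sum()) / (na + nb)


def brute_surface(mask):
    """Boundary voxels by exhaustive 6-neighbour check."""
    out = []
    H, W, L = mask.shape
    for idx in np.argwhere(mask):
        i, j, k = idx
        for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                           (0, 0, 1), (0, 0, -1)):
            ii, jj, kk = i + di, j + dj, k + dk
            if not (0 <= ii < H and 0 <= jj < W and 0 <= kk < L) \
                    or not mask[ii, jj, kk]:
                out.append(idx)
                break
    return np.array(out)


def brute_assd(ma, mb, spacing=(1.0, 1.0, 1.0)):
    sa = brute_surface(ma) * np.asarray(spacing)
    sb = brute_surface(mb) * np.asarray(spacing)
    d = cdist(sa, sb)
    return (d.min(axis=1).sum() + d.min(axis=0).sum()) / (len(sa) + len(sb))
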