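"""Vectorized 3D texture-matrix builders.

All builders take a 3D float array of grey levels (1..n_levels, NaN outside
the ROI).  Directional matrices (GLCM, GLRLM) use the 13 unique 3D directions
at Chebyshev distance 1; zone/dependence matrices (GLSZM, NGLDM) use
26-connectivity; only voxel pairs/neighbourhoods fully inside the ROI
contribute.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

# the 13 unique direction vectors (z, y, x); their negatives complete the 26
DIRECTIONS_13 = (
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def _offset_views(arr, off):
    """Aligned views (a, b) with b displaced by ``off`` relative to a."""
    sl_a, sl_b = [], []
    for n, d in zip(arr.shape, off):
        if d >= 0:
            sl_a.append(slice(0, n - d))
            sl_b.append(slice(d, n))
        else:
            sl_a.append(slice(-d, n))
            sl_b.append(slice(0, n + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _shifted(arr, off, fill=0.0):
    """Array displaced by ``off`` (value at v is arr[v + off]), padded."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    a, b = _offset_views(out, off)
    src_a, src_b = _offset_views(arr, off)
    a[...] = src_b
    return out


def glcm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Symmetric co-occurrence matrix for one direction, raw counts."""
    a, b = _offset_views(levels, direction)
    ok = np.isfinite(a) & np.isfinite(b)
    ia = a[ok].astype(int) - 1
    ib = b[ok].astype(int) - 1
    m = np.bincount(ia * n_levels + ib, minlength=n_levels * n_levels)
    m = m.reshape(n_levels, n_levels).astype(float)
    return m + m.T


def glrlm(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length matrix (levels x max_run) for one direction, raw counts."""
    valid = np.isfinite(levels)
    lv = np.where(valid, levels, 0.0)
    nxt_valid = _shifted(valid.astype(float), direction) > 0.5
    nxt_lv = _shifted(lv, direction)
    same_next = valid & nxt_valid & (lv == nxt_lv)

    neg = tuple(-d for d in direction)
    prv_valid = _shifted(valid.astype(float), neg) > 0.5
    prv_lv = _shifted(lv, neg)
    is_start = valid & ~(prv_valid & (lv == prv_lv))

    # R[v] = 1 + R[v + d] when the next voxel continues the run; propagate
    run = valid.astype(int)
    max_iter = int(np.max(levels.shape))
    for _ in range(max_iter):
        nxt_run = _shifted(run.astype(float), direction).astype(int)
        new = np.where(valid, 1 + np.where(same_next, nxt_run, 0), 0)
        if np.array_equal(new, run):
            break
        run = new

    lv_i = lv[is_start].astype(int) - 1
    rl = run[is_start]
    max_run = int(rl.max()) if rl.size else 1
    m = np.bincount(lv_i * max_run + (rl - 1), minlength=n_levels * max_run)
    return m.reshape(n_levels, max_run).astype(float)


def glszm(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Size-zone matrix (levels x max_zone), zones by 26-connectivity."""
    valid = np.isfinite(levels)
    zones = []  # (level, size)
    for lev in range(1, n_levels + 1):
        sel = valid & (levels == lev)
        if not sel.any():
            continue
        lab, n = ndimage.label(sel, structure=_CONN26)
        sizes = np.bincount(lab.ravel())[1:]
        zones.extend((lev, int(s)) for s in sizes)
    if not zones:
        raise ValueError("no zones: empty ROI")
    max_zone = max(s for _, s in zones)
    m = np.zeros((n_levels, max_zone))
    for lev, s in zones:
        m[lev - 1, s - 1] += 1
    return m


def ngldm(levels: np.ndarray, n_levels: int, alpha: float = 0.0) -> np.ndarray:
    """Dependence matrix (levels x dependence-count), 26-neighbourhood.

    A neighbour is *dependent* when |level difference| <= alpha (default 0,
    i.e. identical level).  Column j corresponds to dependence count j-1
    (count of dependent neighbours), so j runs 1..27.
    """
    valid = np.isfinite(levels)
    lv = np.where(valid, levels, np.nan)
    dep = np.zeros(levels.shape, dtype=int)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-x for x in d)):
            nb = _shifted(lv, off, fill=np.nan)
            dep += (np.abs(nb - lv) <= alpha) & np.isfinite(nb) & valid
    ks = dep[valid]
    ls = lv[valid].astype(int) - 1
    max_k = int(ks.max())
    m = np.bincount(ls * (max_k + 1) + ks, minlength=n_levels * (max_k + 1))
    return m.reshape(n_levels, max_k + 1).astype(float)


def ngtdm(levels: np.ndarray, n_levels: int):
    """Neighbourhood grey-tone difference vectors (s_i, n_i, p_i).

    For every ROI voxel with at least one valid 26-neighbour, the absolute
    difference between its level and the mean level of its valid neighbours
    accumulates into s_i; n_i counts those voxels per level.
    """
    valid = np.isfinite(levels)
    lv = np.where(valid, levels, 0.0)
    nb_sum = np.zeros(levels.shape)
    nb_cnt = np.zeros(levels.shape)
    for d in DIRECTIONS_13:
        for off in (d, tuple(-x for x in d)):
            nb_sum += _shifted(lv, off)
            nb_cnt += _shifted(valid.astype(float), off)
    use = valid & (nb_cnt > 0)
    avg = np.zeros(levels.shape)
    avg[use] = nb_sum[use] / nb_cnt[use]
    diffs = np.abs(lv - avg)
    idx = lv[use].astype(int) - 1
    s = np.bincount(idx, weights=diffs[use], minlength=n_levels)
    n = np.bincount(idx, minlength=n_levels).astype(float)
    p = n / n.sum() if n.sum() else n
    return s, n, p
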