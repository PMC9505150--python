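"""Independent brute-force oracles used by the test suite.

Everything here is written with explicit loops (or a different algorithm
entirely) so it shares no code path with the package implementations it
cross-checks.
"""

from __future__ import annotations

import math

import numpy as np

# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def winding_number_inside(point, polygon) -> bool:
    """Point-in-polygon by summed signed angles (winding number)."""
    px, py = point
    total = 0.0
    n = len(polygon)
    for k in range(n):
        x1, y1 = polygon[k]
        x2, y2 = polygon[(k + 1) % n]
        a1 = math.atan2(y1 - py, x1 - px)
        a2 = math.atan2(y2 - py, x2 - px)
        da = a2 - a1
        while da > math.pi:
            da -= 2 * math.pi
        while da < -math.pi:
            da += 2 * math.pi
        total += da
    return abs(total) > math.pi  # ~2*pi inside, ~0 outside


def trilinear_at(volume, spacing, origin, point):
    """8-corner weighted sum at one physical point (axes ordered z, y, x)."""
    idx = [(p - o) / s for p, o, s in zip(point, origin, spacing)]
    base = [int(math.floor(v)) for v in idx]
    frac = [v - b for v, b in zip(idx, base)]
    total = 0.0
    for dz in (0, 1):
        for dy in (0, 1):
            for dx in (0, 1):
                wz = frac[0] if dz else 1 - frac[0]
                wy = frac[1] if dy else 1 - frac[1]
                wx = frac[2] if dx else 1 - frac[2]
                total += wz * wy * wx * volume[base[0] + dz, base[1] + dy, base[2] + dx]
    return total


# ---------------------------------------------------------------------------
# texture matrices (explicit loops)
# ---------------------------------------------------------------------------

def _valid(levels, z, y, x):
    nz, ny, nx = levels.shape
    return 0 <= z < nz and 0 <= y < ny and 0 <= x < nx and np.isfinite(levels[z, y, x])


def glcm_loop(levels, n_levels, direction):
    m = np.zeros((n_levels, n_levels))
    dz, dy, dx = direction
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not np.isfinite(levels[z, y, x]):
                    continue
                z2, y2, x2 = z + dz, y + dy, x + dx
                if _valid(levels, z2, y2, x2):
                    i = int(levels[z, y, x]) - 1
                    j = int(levels[z2, y2, x2]) - 1
                    m[i, j] += 1
                    m[j, i] += 1
    return m


def glrlm_loop(levels, n_levels, direction):
    runs = []
    dz, dy, dx = direction
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not np.isfinite(levels[z, y, x]):
                    continue
                # only start a run where the previous voxel does not continue it
                pz, py, px = z - dz, y - dy, x - dx
                if _valid(levels, pz, py, px) and levels[pz, py, px] == levels[z, y, x]:
                    continue
                lev = levels[z, y, x]
                length = 1
                cz, cy, cx = z + dz, y + dy, x + dx
                while _valid(levels, cz, cy, cx) and levels[cz, cy, cx] == lev:
                    length += 1
                    cz, cy, cx = cz + dz, cy + dy, cx + dx
                runs.append((int(lev), length))
    max_run = max(l for _, l in runs)
    m = np.zeros((n_levels, max_run))
    for lev, length in runs:
        m[lev - 1, length - 1] += 1
    return m


_OFFSETS_26 = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
               for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]


def glszm_loop(levels, n_levels):
    visited = np.zeros(levels.shape, dtype=bool)
    zones = []
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if visited[z, y, x] or not np.isfinite(levels[z, y, x]):
                    continue
                lev = levels[z, y, x]
                stack = [(z, y, x)]
                visited[z, y, x] = True
                size = 0
                while stack:
                    cz, cy, cx = stack.pop()
                    size += 1
                    for dz, dy, dx in _OFFSETS_26:
                        t = (cz + dz, cy + dy, cx + dx)
                        if _valid(levels, *t) and not visited[t] \
                                and levels[t] == lev:
                            visited[t] = True
                            stack.append(t)
                zones.append((int(lev), size))
    max_zone = max(s for _, s in zones)
    m = np.zeros((n_levels, max_zone))
    for lev, s in zones:
        m[lev - 1, s - 1] += 1
    return m


def ngldm_loop(levels, n_levels, alpha=0.0):
    entries = []
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not np.isfinite(levels[z, y, x]):
                    continue
                k = 0
                for dz, dy, dx in _OFFSETS_26:
                    t = (z + dz, y + dy, x + dx)
                    if _valid(levels, *t) and abs(levels[t] - levels[z, y, x]) <= alpha:
                        k += 1
                entries.append((int(levels[z, y, x]), k))
    max_k = max(k for _, k in entries)
    m = np.zeros((n_levels, max_k + 1))
    for lev, k in entries:
        m[lev - 1, k] += 1
    return m


def ngtdm_loop(levels, n_levels):
    s = np.zeros(n_levels)
    n = np.zeros(n_levels)
    nz, ny, nx = levels.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not np.isfinite(levels[z, y, x]):
                    continue
                nb = [levels[z + dz, y + dy, x + dx] for dz, dy, dx in _OFFSETS_26
                      if _valid(levels, z + dz, y + dy, x + dx)]
                if not nb:
                    continue
                i = int(levels[z, y, x])
                s[i - 1] += abs(i - sum(nb) / len(nb))
                n[i - 1] += 1
    p = n / n.sum() if n.sum() else n
    return s, n, p


# ---------------------------------------------------------------------------
# learning / metrics
# ---------------------------------------------------------------------------

def pairwise_auc(scores, labels):
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def best_single_threshold_error(X, y, sample_weight):
    """Exhaustive search over (feature, threshold, polarity) stumps."""
    best = np.inf
    w = np.asarray(sample_weight, dtype=float)
    w = w / w.sum()
    for f in range(X.shape[1]):
        xs = np.unique(X[:, f])
        cuts = np.concatenate([[-np.inf], (xs[:-1] + xs[1:]) / 2, [np.inf]])
        for c in cuts:
            pred = np.where(X[:, f] <= c, 1, -1)
            for pol in (1, -1):
                err = w[(pol * pred) != y].sum()
                best = min(best, err)
    return best


def nca_objective_fullbatch_gd(X, y, lam, n_iter=400, lr=0.1):
    """Full-batch gradient ascent on the regularized NCA objective.

    Returns the best objective value reached; independent optimizer used to
    benchmark the SGD solver's solution quality.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    w = np.full(p, 1.0 / np.sqrt(p))

    def objective(w):
        w2 = w ** 2
        tot = 0.0
        for i in range(n):
            d = np.abs(X - X[i]) @ w2
            d[i] = np.inf
            e = np.exp(-(d - d.min()))
            pij = e / e.sum()
            tot += pij[(y == y[i])].sum() - pij[i]
        return tot - lam * w2.sum()

    best = objective(w)
    for _ in range(n_iter):
        grad = np.zeros(p)
        for i in range(n):
            diff = np.abs(X - X[i])
            d = diff @ (w ** 2)
            d[i] = np.inf
            e = np.exp(-(d - d.min()))
            pij = e / e.sum()
            pij[i] = 0.0
            same = (y == y[i])
            same[i] = False
            p_i = pij[same].sum()
            grad += 2 * w * (p_i * (pij @ diff) - (pij[same] @ diff[same]))
        grad -= 2 * lam * w
        w = w + lr * grad
        best = max(best, objective(w))
    return best
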