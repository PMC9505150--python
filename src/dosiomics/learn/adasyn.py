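"""ADASYN oversampling for binary imbalanced problems.

Synthesizes minority samples preferentially near the class boundary: the
number of synthetic points seeded at each minority sample is proportional to
the fraction of majority samples among its k nearest neighbours.  Original
rows are preserved verbatim.
"""

from __future__ import annotations

import warnings

import numpy as np
from sklearn.neighbors import NearestNeighbors


def _largest_remainder(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing exactly to ``total`` (largest remainder)."""
    raw = fractions * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def adasyn(X: np.ndarray, y: np.ndarray, k: int = 5, beta: float = 1.0,
           rng: np.random.Generator | None = None):
    """Return (X', y') with G = (n_maj - n_min) * beta synthetic minority rows.

    Expects standardized features.  Each synthetic point is a uniform convex
    combination x_i + u * (x_z - x_i) of a minority seed and one of its
    minority k-nearest neighbours.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("adasyn needs exactly two classes present")
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_min = len(X_min)
    n_maj = len(X) - n_min
    if n_min < 2:
        raise ValueError("need at least 2 minority samples")
    G = int(round((n_maj - n_min) * beta))
    if G <= 0:
        return X.copy(), y.copy()

    k_eff = min(k, len(X) - 1)
    nn_all = NearestNeighbors(n_neighbors=k_eff + 1).fit(X)
    _, idx = nn_all.kneighbors(X_min)
    neigh = idx[:, 1:]  # drop self
    r = (y[neigh] != minority).mean(axis=1)
    if r.sum() == 0:
        warnings.warn("minority class isolated from majority; uniform allocation")
        r_hat = np.full(n_min, 1.0 / n_min)
    else:
        r_hat = r / r.sum()
    g = _largest_remainder(r_hat, G)

    k_min = min(k, n_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k_min + 1).fit(X_min)
    _, min_idx = nn_min.kneighbors(X_min)
    min_neigh = min_idx[:, 1:]

    synth = []
    for i in range(n_min):
        for _ in range(g[i]):
            z = min_neigh[i][rng.integers(k_min)]
            lam = rng.uniform()
            synth.append(X_min[i] + lam * (X_min[z] - X_min[i]))
    X_out = np.vstack([X, np.asarray(synth)]) if synth else X.copy()
    y_out = np.concatenate([y, np.full(len(synth), minority, dtype=y.dtype)])
    return X_out, y_out
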