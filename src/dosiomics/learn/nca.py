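"""Regularized neighbourhood component analysis (NCA) feature weighting.

Maximizes  sum_i p_i - lambda * sum_r w_r^2  where
p_i = sum_{j != i, y_j = y_i} p_ij  and
p_ij = exp(-d_ij) / sum_{k != i} exp(-d_ik),
d_ij = sum_r w_r^2 |x_ir - x_jr|   (weighted L1 distance).

p_i is the soft leave-one-out probability that sample i is correctly
classified by a stochastic nearest neighbour, so the objective is one minus
the (regularized) expected leave-one-out error.  Solved by per-sample
stochastic gradient ascent with a 1/(1 + decay * epoch) learning-rate
schedule; returns |w_r| so weights are non-negative.
"""

from __future__ import annotations

import numpy as np


def _softmax_neg(d):
    """exp(-d) normalized, numerically stable."""
    e = np.exp(-(d - d.min()))
    return e / e.sum()


def nca_objective(w: np.ndarray, X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Full-batch value of the regularized NCA objective."""
    w2 = w ** 2
    n = len(X)
    total = 0.0
    for i in range(n):
        diff = np.abs(X - X[i])
        d = diff @ w2
        d[i] = np.inf
        p = _softmax_neg(np.delete(d, i))
        same = np.delete(y == y[i], i)
        total += p[same].sum()
    return total - lam * float(w2.sum())


def nca_weights(X: np.ndarray, y: np.ndarray, lam: float = 0.02,
                n_epochs: int = 8, learning_rate: float = 0.3,
                decay: float = 0.2, rng: np.random.Generator | None = None,
                ) -> np.ndarray:
    """Per-feature non-negative weights; deterministic given the rng state."""
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p_dim = X.shape
    for cls in np.unique(y):
        if (y == cls).sum() < 2:
            raise ValueError("need at least 2 samples per class")
    # start on the soft-neighbour scale: with p features of unit spread,
    # w0 = 1/sqrt(p) keeps initial pairwise distances O(1) so the softmax
    # is not frozen onto single nearest neighbours
    w = np.full(p_dim, 1.0 / np.sqrt(p_dim))
    for epoch in range(n_epochs):
        lr = learning_rate / (1.0 + decay * epoch)
        for i in rng.permutation(n):
            diff = np.abs(X - X[i])          # (n, p)
            d = diff @ (w ** 2)
            d[i] = np.inf
            pij = _softmax_neg(d)
            pij[i] = 0.0
            same = (y == y[i])
            same[i] = False
            p_i = pij[same].sum()
            # d p_i / d w_r = 2 w_r (p_i * sum_j pij |diff| - sum_{same} pij |diff|)
            weighted_all = pij @ diff
            weighted_same = pij[same] @ diff[same]
            grad = 2.0 * w * (p_i * weighted_all - weighted_same)
            # explicit ascent on the neighbour term, proximal (implicit)
            # shrinkage for the L2 penalty -- stable for any lambda
            w = (w + lr * grad) / (1.0 + 2.0 * lr * lam / n)
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(
                    f"non-finite NCA weights at epoch {epoch}, sample {i}")
    return np.abs(w)


def select_top(weights: np.ndarray, m: int) -> np.ndarray:
    """Indices of the m largest weights, descending; ties to the lower index."""
    weights = np.asarray(weights)
    if not 1 <= m <= len(weights):
        raise ValueError("m out of range")
    order = np.argsort(-weights, kind="stable")
    return order[:m]
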