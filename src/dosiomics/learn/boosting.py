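"""Boosting ensembles: RobustBoost (default) and a plain AdaBoost comparator.

RobustBoost is a continuous-time boost-by-majority variant designed to
tolerate label noise.  Each example carries a real-valued margin m_i; the
algorithm runs in self-time t from 0 to 1 and weights examples by a Gaussian
potential centred on a drifting target margin:

    sigma(t)^2 = (sigma_f^2 + 1) * exp(2 (1 - t)) - 1
    mu(t)      = (theta - 2 rho) * exp(1 - t) + 2 rho
    w_i(t)     = exp(-(m_i - mu(t))^2 / (2 sigma(t)^2))

rho is calibrated from the target error ``error_goal`` so that the initial
potential of a zero-margin example equals the goal.  Every cycle fits a weak
tree to the current weights and then advances: the time step dt and the
learner coefficient alpha are found numerically so that the mean potential
is conserved while the weighted edge of the new state vanishes (the step is
the largest feasible one).  Training stops at t >= 1, at the cycle budget,
or when no feasible step remains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .config import LearnConfig
from .trees import WeakTree


def _rho(error_goal: float, sigma_f: float, theta: float) -> float:
    sigma0 = np.sqrt((sigma_f ** 2 + 1.0) * np.e ** 2 - 1.0)
    mu0 = -np.sqrt(2.0) * sigma0 * special.erfcinv(2.0 * error_goal)
    return (mu0 - theta * np.e) / (2.0 * (1.0 - np.e))


@dataclass
class EnsembleModel:
    """A weighted-vote ensemble over a feature subset.

    ``feature_idx`` indexes into the full feature table; ``mu``/``sigma``
    are the training-fold standardization parameters for those features.
    Positive score means positive class; ties predict negative.
    """

    learners: list = field(default_factory=list)   # (WeakTree, alpha)
    feature_idx: np.ndarray = None
    feature_names: list = None
    mu: np.ndarray = None
    sigma: np.ndarray = None
    algorithm: str = "robustboost"

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        if self.feature_idx is not None:
            if X.shape[1] < int(np.max(self.feature_idx)) + 1:
                raise ValueError("input table lacks the model's feature columns")
            X = X[:, self.feature_idx]
        if self.mu is not None:
            X = (X - self.mu) / self.sigma
        return X

    def predict_score(self, X) -> np.ndarray:
        """Weighted vote sum_k alpha_k h_k(x)."""
        if not self.learners:
            raise ValueError("empty ensemble")
        X = self._prepare(X)
        score = np.zeros(len(X))
        for tree, alpha in self.learners:
            score += alpha * tree.predict(X)
        return score

    def predict_label(self, X) -> np.ndarray:
        """+1 / -1 labels; a zero score falls to the negative class."""
        return np.where(self.predict_score(X) > 0, 1, -1)

    def to_json(self) -> str:
        return json.dumps({
            "algorithm": self.algorithm,
            "feature_idx": None if self.feature_idx is None
                           else np.asarray(self.feature_idx).tolist(),
            "feature_names": self.feature_names,
            "mu": None if self.mu is None else np.asarray(self.mu).tolist(),
            "sigma": None if self.sigma is None else np.asarray(self.sigma).tolist(),
            "learners": [{"alpha": float(a), "tree": t.to_dict()}
                         for t, a in self.learners],
        })

    @classmethod
    def from_json(cls, payload: str) -> "EnsembleModel":
        d = json.loads(payload)
        return cls(
            learners=[(WeakTree.from_dict(rec["tree"]), rec["alpha"])
                      for rec in d["learners"]],
            feature_idx=None if d["feature_idx"] is None else np.asarray(d["feature_idx"]),
            feature_names=d["feature_names"],
            mu=None if d["mu"] is None else np.asarray(d["mu"]),
            sigma=None if d["sigma"] is None else np.asarray(d["sigma"]),
            algorithm=d["algorithm"],
        )


def _as_pm1(y) -> np.ndarray:
    y = np.asarray(y)
    if y.dtype == bool:
        return np.where(y, 1, -1)
    vals = np.unique(y)
    if set(vals.tolist()) <= {-1, 1}:
        return y.astype(int)
    if set(vals.tolist()) <= {0, 1}:
        return np.where(y == 1, 1, -1)
    raise ValueError("labels must be boolean, 0/1 or -1/+1")


def fit_robustboost(X, y, config: LearnConfig = None,
                    rng: np.random.Generator | None = None,
                    sigma_f: float = 0.1, theta: float = 0.0) -> EnsembleModel:
    """Fit a RobustBoost ensemble of shallow trees (deterministic given rng)."""
    config = config or LearnConfig()
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    yy = _as_pm1(y)
    n = len(yy)
    model = EnsembleModel(algorithm="robustboost")
    if len(np.unique(yy)) < 2:
        tree = WeakTree.fit(X, yy, max_splits=0)
        model.learners.append((tree, 1.0))
        return model

    rho = _rho(config.boost_error_goal, sigma_f, theta)

    def mu_t(t):
        return (theta - 2.0 * rho) * np.exp(1.0 - t) + 2.0 * rho

    def sig_t(t):
        return np.sqrt((sigma_f ** 2 + 1.0) * np.exp(2.0 * (1.0 - t)) - 1.0)

    def potential(m, t):
        return 0.5 * special.erfc((m - mu_t(t)) / (np.sqrt(2.0) * sig_t(t)))

    def weights(m, t):
        return np.exp(-(m - mu_t(t)) ** 2 / (2.0 * sig_t(t) ** 2))

    margins = np.zeros(n)
    t = 0.0
    failures = 0
    t_eps = 1e-9
    for cycle in range(config.boost_max_cycles):
        if t >= 1.0 - t_eps:
            break
        w = weights(margins, t)
        if w.sum() < 1e-12:
            break
        tree = WeakTree.fit(X, yy, sample_weight=w / w.sum(),
                            max_splits=config.tree_max_splits,
                            random_state=int(rng.integers(2 ** 31 - 1)))
        h = tree.predict(X).astype(float)
        agree = yy * h

        pot_now = potential(margins, t).mean()

        def edge(alpha, dt):
            wn = weights(margins + alpha * agree, t + dt)
            return float((wn * agree).sum())

        def solve_alpha(dt):
            """Root of the weighted edge in alpha for a fixed time step."""
            lo, hi = 1e-8, 0.25
            e_lo = edge(lo, dt)
            if e_lo <= 0:
                return None
            while edge(hi, dt) > 0 and hi < 64:
                hi *= 2.0
            if edge(hi, dt) > 0:
                return None
            return optimize.brentq(lambda a: edge(a, dt), lo, hi,
                                   xtol=1e-5, maxiter=60)

        def pot_gap(dt):
            alpha = solve_alpha(dt)
            if alpha is None:
                return None, None
            gap = potential(margins + alpha * agree, t + dt).mean() - pot_now
            return alpha, gap

        # largest feasible time step by geometric halving of the target step
        step = None
        dt = 1.0 - t
        for _ in range(14):
            alpha_c, gap_c = pot_gap(dt)
            if alpha_c is not None and gap_c <= 1e-12:
                step = (alpha_c, dt)
                break
            dt *= 0.5
        if step is None:
            failures += 1
            if failures >= 3:
                warnings.warn("RobustBoost: no feasible step; stopping early "
                              f"at t={t:.3f} after {cycle} cycles")
                break
            continue
        failures = 0
        alpha, dt = step
        if dt < 1e-7:
            warnings.warn(f"RobustBoost: time stalled at t={t:.3f}; stopping")
            break
        margins = margins + alpha * agree
        t += dt
        model.learners.append((tree, float(alpha)))
    if not model.learners:
        tree = WeakTree.fit(X, yy, max_splits=0)
        model.learners.append((tree, 1.0))
    return model


def fit_adaboost(X, y, config: LearnConfig = None,
                 rng: np.random.Generator | None = None) -> EnsembleModel:
    """Discrete AdaBoost over the same weak learners (comparator, not default)."""
    config = config or LearnConfig()
    rng = rng or np.random.default_rng()
    X = np.asarray(X, dtype=float)
    yy = _as_pm1(y)
    n = len(yy)
    model = EnsembleModel(algorithm="adaboost")
    if len(np.unique(yy)) < 2:
        model.learners.append((WeakTree.fit(X, yy, max_splits=0), 1.0))
        return model
    w = np.full(n, 1.0 / n)
    for _ in range(config.boost_max_cycles):
        tree = WeakTree.fit(X, yy, sample_weight=w,
                            max_splits=config.tree_max_splits,
                            random_state=int(rng.integers(2 ** 31 - 1)))
        h = tree.predict(X)
        err = float(w[h != yy].sum())
        if err >= 0.5:
            break
        err = max(err, 1e-10)
        alpha = 0.5 * np.log((1.0 - err) / err)
        model.learners.append((tree, alpha))
        w = w * np.exp(-alpha * yy * h)
        w /= w.sum()
        if err <= 1e-10:
            break
    if not model.learners:
        model.learners.append((WeakTree.fit(X, yy, max_splits=0), 1.0))
    return model
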