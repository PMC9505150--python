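"""Outcome binarization and leakage-safe repeated cross-validation.

Each repetition draws a fresh stratified 10-fold partition.  Inside every
fold, standardization, ADASYN oversampling, NCA feature weighting and
ensemble fitting see only the training indices; the test fold is scored
untouched.  Per repetition the 10 test folds' predictions are pooled into
one set of scores, from which sensitivity, specificity, accuracy (threshold
0 on the vote score) and trapezoidal AUC are computed; means and standard
deviations are reported over repetitions for each feature count m.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .learn import (EnsembleModel, LearnConfig, adasyn, fit_robustboost,
                    nca_weights, select_top)

log = logging.getLogger(__name__)

HORIZON_MONTHS = 36.0


@dataclass
class OutcomeLabel:
    patient_id: str
    label: bool
    horizon_months: float = HORIZON_MONTHS


def binarize_outcome(time_months: float, event: bool,
                     horizon_months: float = HORIZON_MONTHS,
                     patient_id: str = "") -> OutcomeLabel:
    """Positive iff the failure event occurred within the horizon.

    Event-free follow-up shorter than the horizon counts as negative — the
    acknowledged simplification of a fixed-horizon binarization (late
    relapses are labelled relapse-free).
    """
    if time_months <= 0:
        raise ValueError("time_months must be positive")
    return OutcomeLabel(patient_id, bool(event) and time_months <= horizon_months,
                        horizon_months)


@dataclass
class CVConfig:
    n_folds: int = 10
    n_repeats: int = 100
    max_features: int = 8
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_folds < 2 or self.max_features < 1:
            raise ValueError("n_folds >= 2 and max_features >= 1 required")


@dataclass
class CVReport:
    """Aggregated repeated-CV results.

    ``metric_mean``/``metric_std`` are DataFrames indexed by feature count m
    with columns sensitivity/specificity/accuracy/auc; ``selection_frequency``
    counts how often each feature entered the top-m* subset over all
    folds x repeats; ``roc_points`` are pooled (fpr, tpr) pairs at m*.
    """

    metric_mean: pd.DataFrame
    metric_std: pd.DataFrame
    best_m: int
    selection_frequency: pd.Series
    roc_points: np.ndarray
    per_repetition: pd.DataFrame = field(default=None, repr=False)


def make_folds(labels, n_folds: int, rng, stratified: bool = True) -> list:
    """Disjoint test-index sets covering every sample exactly once."""
    labels = np.asarray(labels).astype(int)
    if len(labels) < n_folds:
        raise ValueError("fewer samples than folds")
    seed = int(rng.integers(2 ** 31 - 1))
    if stratified:
        counts = np.bincount(labels, minlength=2)
        if counts.min() < n_folds:
            warnings.warn("a class is smaller than n_folds; stratification is "
                          "approximate")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)), labels)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split = splitter.split(np.zeros(len(labels)))
    return [test for _, test in split]


def metrics(scores, labels, threshold: float = 0.0):
    """(sensitivity, specificity, accuracy) at a score threshold.

    A score strictly above the threshold predicts positive.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("need both classes to compute sensitivity/specificity")
    pred = scores > threshold
    tp = int((pred & labels).sum())
    tn = int((~pred & ~labels).sum())
    fp = int((pred & ~labels).sum())
    fn = int((~pred & labels).sum())
    return tp / (tp + fn), tn / (tn + fp), (tp + tn) / len(labels)


def roc_auc(scores, labels):
    """Trapezoidal AUC plus the ROC points; ties count one half.

    Equivalent to the normalized Mann-Whitney U statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if labels.all() or not labels.any():
        raise ValueError("need both classes for a ROC curve")
    fpr, tpr, _ = roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, np.column_stack([fpr, tpr])


def pick_best(metric_mean: pd.DataFrame) -> int:
    """Feature count with the highest mean accuracy; ties to the smaller m."""
    acc = metric_mean["accuracy"]
    return int(acc.index[np.argmax(acc.values)])


def _fit_fold(X, y, train_idx, feature_names, learn_config, rng):
    """Standardize -> ADASYN -> NCA on the training rows only."""
    Xtr = X[train_idx]
    ytr = y[train_idx]
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    Ztr = (Xtr - mu) / sd
    Za, ya = adasyn(Ztr, ytr, k=learn_config.adasyn_k,
                    beta=learn_config.adasyn_balance, rng=rng)
    if learn_config.nca_on_augmented:
        Xw, yw = Za, ya
    else:
        Xw, yw = Ztr, ytr
    w = nca_weights(Xw, yw, lam=learn_config.nca_lambda,
                    n_epochs=learn_config.nca_epochs,
                    learning_rate=learn_config.nca_learning_rate,
                    decay=learn_config.nca_decay, rng=rng)
    order = select_top(w, len(w))
    return mu, sd, Za, ya, order


def run_repeated_cv(features: pd.DataFrame, labels,
                    learn_config: LearnConfig = None,
                    cv_config: CVConfig = None) -> CVReport:
    """The repeated leakage-safe CV over feature counts 1..max_features."""
    learn_config = learn_config or LearnConfig()
    cv_config = cv_config or CVConfig()
    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    y = np.asarray([l.label if isinstance(l, OutcomeLabel) else l
                    for l in labels]).astype(int)
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    rng = np.random.default_rng(cv_config.seed)
    n = len(y)
    ms = range(1, cv_config.max_features + 1)

    rep_rows = []
    selected_per_m = {m: [] for m in ms}  # list of index arrays, folds x repeats
    pooled_scores = {m: [] for m in ms}
    pooled_labels = []

    for rep in range(cv_config.n_repeats):
        for _redraw in range(20):
            folds = make_folds(y, cv_config.n_folds, rng, cv_config.stratified)
            ok = all(len(np.unique(y[np.setdiff1d(np.arange(n), f)])) == 2
                     for f in folds)
            if ok:
                break
            log.warning("degenerate split in repetition %d; re-drawing folds", rep)
        scores_m = {m: np.zeros(n) for m in ms}
        for test_idx in folds:
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            assert np.intersect1d(train_idx, test_idx).size == 0  # leakage guard
            mu, sd, Za, ya, order = _fit_fold(X, y, train_idx, names,
                                              learn_config, rng)
            Zte = (X[test_idx] - mu) / sd
            for m in ms:
                idx = order[:m]
                selected_per_m[m].append(idx)
                model = fit_robustboost(Za[:, idx], ya, learn_config, rng)
                scores_m[m][test_idx] = model.predict_score(Zte[:, idx])
        for m in ms:
            sens, spec, acc = metrics(scores_m[m], y)
            auc, _ = roc_auc(scores_m[m], y)
            prev = y.mean()
            assert abs(acc - (prev * sens + (1 - prev) * spec)) < 1e-9
            rep_rows.append({"repetition": rep, "m": m, "sensitivity": sens,
                             "specificity": spec, "accuracy": acc, "auc": auc})
            pooled_scores[m].append(scores_m[m])
        pooled_labels.append(y)

    per_rep = pd.DataFrame(rep_rows)
    grouped = per_rep.groupby("m")[["sensitivity", "specificity", "accuracy", "auc"]]
    metric_mean = grouped.mean()
    metric_std = grouped.std(ddof=0)
    best_m = pick_best(metric_mean)

    counts = np.zeros(len(names), dtype=int)
    for idx in selected_per_m[best_m]:
        counts[idx] += 1
    freq = pd.Series(counts, index=names).sort_values(ascending=False)
    freq = freq[freq > 0]

    all_scores = np.concatenate(pooled_scores[best_m])
    all_labels = np.concatenate(pooled_labels)
    _, roc_pts = roc_auc(all_scores, all_labels)
    return CVReport(metric_mean, metric_std, best_m, freq, roc_pts, per_rep)
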