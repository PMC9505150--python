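"""Shallow decision-tree weak learners.

Thin wrapper over scikit-learn's CART: ``max_leaf_nodes = max_splits + 1``
grows the tree best-first on weighted Gini impurity with at most
``max_splits`` internal splits, which is exactly the weak-learner contract
used by the boosting ensemble.  Labels are internally -1/+1; leaf scores are
the weighted class-probability difference.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier


class WeakTree:
    """A <=``max_splits``-split binary classification tree over -1/+1 labels."""

    def __init__(self, clf=None, nodes=None, constant=None):
        self._clf = clf
        self._nodes = nodes
        self._constant = constant

    # -- fitting ----------------------------------------------------------
    @classmethod
    def fit(cls, X, y, sample_weight=None, max_splits: int = 4,
            random_state: int = 0) -> "WeakTree":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if sample_weight is not None:
            sample_weight = np.asarray(sample_weight, dtype=float)
            if np.any(sample_weight < 0) or sample_weight.sum() == 0:
                raise ValueError("sample weights must be >= 0 and not all zero")
        if len(np.unique(y)) < 2 or max_splits == 0:
            return cls(constant=_weighted_majority(y, sample_weight))
        clf = DecisionTreeClassifier(criterion="gini",
                                     max_leaf_nodes=max_splits + 1,
                                     random_state=random_state)
        clf.fit(X, y, sample_weight=sample_weight)
        return cls(clf=clf)

    # -- prediction -------------------------------------------------------
    def predict(self, X) -> np.ndarray:
        """Hard -1/+1 labels (leaf ties resolve to -1)."""
        return np.where(self.score(X) > 0, 1, -1)

    def score(self, X) -> np.ndarray:
        """Leaf score: weighted p(+1) - p(-1) in [-1, 1]."""
        X = np.asarray(X, dtype=float)
        if self._constant is not None:
            return np.full(len(X), float(self._constant))
        if self._clf is not None:
            proba = self._clf.predict_proba(X)
            pos = list(self._clf.classes_).index(1) if 1 in self._clf.classes_ else None
            if pos is None:
                return np.full(len(X), -1.0)
            return 2.0 * proba[:, pos] - 1.0
        return np.array([_eval_nodes(self._nodes, row) for row in X])

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        if self._constant is not None:
            return {"leaf": True, "score": float(self._constant)}
        if self._nodes is not None:
            return self._nodes
        t = self._clf.tree_
        classes = list(self._clf.classes_)

        def walk(node):
            if t.children_left[node] == -1:
                counts = t.value[node][0] * t.weighted_n_node_samples[node]
                pos = counts[classes.index(1)] if 1 in classes else 0.0
                neg = counts[classes.index(-1)] if -1 in classes else 0.0
                score = (pos - neg) / (pos + neg) if (pos + neg) > 0 else 0.0
                return {"leaf": True, "score": float(score)}
            return {"leaf": False, "feature": int(t.feature[node]),
                    "threshold": float(t.threshold[node]),
                    "left": walk(t.children_left[node]),
                    "right": walk(t.children_right[node])}

        return walk(0)

    @classmethod
    def from_dict(cls, d: dict) -> "WeakTree":
        if d.get("leaf") and "feature" not in d:
            return cls(nodes=d)
        return cls(nodes=d)


def _weighted_majority(y, sample_weight):
    w = np.ones(len(y)) if sample_weight is None else sample_weight
    pos = w[y == 1].sum()
    neg = w[y == -1].sum()
    tot = pos + neg
    return (pos - neg) / tot if tot > 0 else -1.0


def _eval_nodes(node, row):
    while not node["leaf"]:
        node = node["left"] if row[node["feature"]] <= node["threshold"] else node["right"]
    return node["score"]


def fit_weak_tree(X, y, sample_weight=None, max_splits: int = 4,
                  random_state: int = 0) -> WeakTree:
    """Module-level convenience mirroring :meth:`WeakTree.fit`."""
    return WeakTree.fit(X, y, sample_weight, max_splits, random_state)
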