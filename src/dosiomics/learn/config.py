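"""Configuration of the learning stack."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class LearnConfig:
    """Hyper-parameters of the ADASYN -> NCA -> RobustBoost stack.

    Defaults follow the published procedure: NCA regularization 0.02,
    RobustBoost 5% error goal with at most 500 learning cycles and 4-split
    weak trees.  ADASYN's k and balance target are package choices (k = 5,
    full balancing); NCA runs on the ADASYN-augmented training fold
    (switchable with ``nca_on_augmented``).
    """

    adasyn_k: int = 5
    adasyn_balance: float = 1.0
    nca_lambda: float = 0.02
    nca_epochs: int = 8
    nca_learning_rate: float = 0.3
    nca_decay: float = 0.2
    boost_error_goal: float = 0.05
    boost_max_cycles: int = 500
    tree_max_splits: int = 4
    nca_on_augmented: bool = True

    def __post_init__(self):
        if self.adasyn_k < 1 or self.boost_max_cycles < 1 or self.tree_max_splits < 0:
            raise ValueError("counts must be >= 1 (tree_max_splits >= 0)")
        if not 0 < self.adasyn_balance <= 1:
            raise ValueError("adasyn_balance must be in (0, 1]")
        if not 0 < self.boost_error_goal < 0.5:
            raise ValueError("boost_error_goal must be in (0, 0.5)")
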