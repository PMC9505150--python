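"""Leakage-safe repeated cross-validation on a small phantom cohort.

Inside every fold: z-scoring, ADASYN oversampling and NCA feature weighting
are fit on the training rows only; RobustBoost tree ensembles are trained
for feature counts m = 1..4 and scored on the untouched test fold.  Scores
are pooled per repetition into sensitivity / specificity / accuracy / AUC.

Scaled down (n = 60 patients, 5 repetitions) to run in about a minute; the
full procedure uses 100 repetitions of 10-fold CV with up to 8 features.
"""

import numpy as np

from dosiomics import CVConfig, LearnConfig, PhantomParams, generate_cohort
from dosiomics.cv import binarize_outcome, run_repeated_cv
from dosiomics.features import extract_cohort

params = PhantomParams(n_patients=60, effect_size=2.0, seed=21)
cohort = generate_cohort(params)
features = extract_cohort(cohort)
labels = [binarize_outcome(r.time_months, r.event).label for r in cohort]

report = run_repeated_cv(
    features, labels,
    LearnConfig(),
    CVConfig(n_folds=10, n_repeats=5, max_features=4, seed=1),
)

print("mean metrics over repetitions (rows = number of selected features):")
print(report.metric_mean.round(3))
print(f"\nbest feature count by accuracy: m* = {report.best_m}")
print("most frequently selected features at m*:")
print(report.selection_frequency.head(5).to_string())
# A mean AUC well above 0.5 with BED-prefixed features at the top of the
# selection histogram shows the planted dose-texture signal is recovered;
# with permuted labels the same pipeline stays at chance level.
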