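"""Report figures: ROC curve, metric-vs-feature-count curves, selection histogram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_roc(report, path):
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    pts = report.roc_points
    auc = report.metric_mean.loc[report.best_m, "auc"]
    ax.plot(pts[:, 0], pts[:, 1], lw=1.5,
            label=f"pooled ROC (m={report.best_m}, mean AUC={auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_metrics_vs_m(report, path):
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for col in ("sensitivity", "specificity", "accuracy", "auc"):
        ax.errorbar(report.metric_mean.index, report.metric_mean[col],
                    yerr=report.metric_std[col], label=col, capsize=2, lw=1.2)
    ax.set_xlabel("number of selected features")
    ax.set_ylabel("score (mean ± σ over repetitions)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_selection_frequency(report, path, top: int = 15):
    freq = report.selection_frequency.head(top)[::-1]
    fig, ax = plt.subplots(figsize=(6, 0.3 * len(freq) + 1.5))
    ax.barh(range(len(freq)), freq.values)
    ax.set_yticks(range(len(freq)), freq.index, fontsize=7)
    ax.set_xlabel(f"selections over folds × repeats (m = {report.best_m})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
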