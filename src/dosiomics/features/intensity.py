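"""Intensity statistics, intensity-histogram features and integrated intensity.

Conventions: population variance (divide by N), Fisher (excess) kurtosis,
skewness/kurtosis of a constant ROI defined as 0, histogram entropy in bits,
mode ties resolved to the lowest grey level.
"""

from __future__ import annotations

import numpy as np

from ..imaging import ImageVolume, RoiMask
from .catalogue import HISTOGRAM_FEATURES, STAT_FEATURES


def _roi_values(masked: ImageVolume) -> np.ndarray:
    vals = masked.values[np.isfinite(masked.values)]
    if vals.size == 0:
        raise ValueError("empty ROI")
    return vals


def _spread_stats(x: np.ndarray) -> dict:
    """Statistics shared by the intensity and histogram families."""
    n = x.size
    mean = float(x.mean())
    var = float(x.var())  # population form
    sd = np.sqrt(var)
    if sd > 0:
        skew = float(((x - mean) ** 3).mean() / sd ** 3)
        kurt = float(((x - mean) ** 4).mean() / sd ** 4 - 3.0)
    else:
        skew = kurt = 0.0
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    in_band = x[(x >= p10) & (x <= p90)]
    robust_mad = float(np.abs(in_band - in_band.mean()).mean()) if in_band.size else 0.0
    qcod = float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0
    return {
        "mean": mean, "variance": var, "skewness": skew, "kurtosis": kurt,
        "median": float(med), "minimum": float(x.min()), "p10": float(p10),
        "p90": float(p90), "maximum": float(x.max()),
        "interquartile_range": float(q3 - q1),
        "range": float(x.max() - x.min()),
        "mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "robust_mean_absolute_deviation": robust_mad,
        "median_absolute_deviation": float(np.abs(x - med).mean()),
        "coefficient_of_variation": sd / mean if mean != 0 else 0.0,
        "quartile_coefficient_of_dispersion": qcod,
    }


def intensity_statistics(masked: ImageVolume) -> dict:
    """The 18 first-order statistics of the non-NaN ROI intensities."""
    x = _roi_values(masked)
    vals = _spread_stats(x)
    vals["energy"] = float((x ** 2).sum())
    vals["root_mean_square"] = float(np.sqrt((x ** 2).mean()))
    assert set(vals) == set(STAT_FEATURES)
    return vals


def integrated_intensity(masked: ImageVolume, mask: RoiMask) -> float:
    """Mean ROI intensity times the voxel-count ROI volume in mm^3."""
    x = _roi_values(masked)
    vol = mask.voxel_count() * float(np.prod(mask.spacing_mm))
    return float(x.mean()) * vol


def histogram_features(discretized: ImageVolume, n_levels: int = 64) -> dict:
    """The 23 intensity-histogram features of the discretized ROI."""
    x = _roi_values(discretized)
    if x.min() < 1 or x.max() > n_levels:
        raise ValueError("grey levels outside 1..n_levels")
    vals = _spread_stats(x)
    counts = np.bincount(x.astype(int), minlength=n_levels + 1)[1:].astype(float)
    p = counts / counts.sum()
    nz = p > 0
    vals["mode"] = float(np.argmax(counts) + 1)  # argmax takes the lowest tie
    vals["entropy"] = float(-(p[nz] * np.log2(p[nz])).sum())
    vals["uniformity"] = float((p ** 2).sum())
    grad = np.gradient(counts)
    vals["max_histogram_gradient"] = float(grad.max())
    vals["max_histogram_gradient_level"] = float(np.argmax(grad) + 1)
    vals["min_histogram_gradient"] = float(grad.min())
    vals["min_histogram_gradient_level"] = float(np.argmin(grad) + 1)
    assert set(vals) == set(HISTOGRAM_FEATURES)
    return vals
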