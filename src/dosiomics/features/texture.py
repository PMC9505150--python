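"""IBSI texture features computed from the matrices in :mod:`.matrices`.

Directional families (GLCM, GLRLM) are computed per direction and averaged
over the 13 unique directions; GLSZM, NGTDM and NGLDM are direction-free.
Degenerate conventions: a constant ROI gives GLCM correlation 1 and zero
spread features; entropy terms use 0·log 0 = 0.
"""

from __future__ import annotations

import numpy as np

from . import matrices
from .catalogue import (GLCM_FEATURES, GLRLM_FEATURES, GLSZM_FEATURES,
                        NGLDM_FEATURES, NGTDM_FEATURES)


def _xlog2(p):
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def glcm_features_single(counts: np.ndarray) -> dict:
    """The 25 co-occurrence features from one (symmetric) count matrix."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix: no valid voxel pairs")
    p = counts / total
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    mu = float((ii * p).sum())
    sigma2 = float((pi * (i - (pi * i).sum()) ** 2).sum())

    k_diff = np.arange(n)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    da = float((k_diff * p_diff).sum())
    k_sum = np.arange(2, 2 * n + 1)
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(),
                        minlength=2 * n + 1)[2:]
    sa = float((k_sum * p_sum).sum())

    hxy = float(-_xlog2(p).sum())
    hx = float(-_xlog2(pi).sum())
    pipj = np.outer(pi, pi)
    hxy1 = float(-(p * np.where(pipj > 0, np.log2(np.where(pipj > 0, pipj, 1)), 0)).sum())
    hxy2 = float(-_xlog2(pipj).sum())

    off = ii != jj
    corr = 1.0 if sigma2 == 0 else (float((ii * jj * p).sum()) - mu ** 2) / sigma2
    ic2_arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    return {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float(((ii - mu) ** 2 * p).sum()),
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": float(-_xlog2(p_diff).sum()),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": float(-_xlog2(p_sum).sum()),
        "angular_second_moment": float((p ** 2).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "inverse_difference_normalized": float((p / (1.0 + np.abs(ii - jj) / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "inverse_difference_moment_normalized":
            float((p / (1.0 + (ii - jj) ** 2 / n ** 2)).sum()),
        "inverse_variance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation_1": 0.0 if hx == 0 else (hxy - hxy1) / hx,
        "information_correlation_2": float(np.sqrt(max(ic2_arg, 0.0))),
    }


def _rl_style_features(m: np.ndarray, n_voxels: int, prefix: str) -> dict:
    """Shared run-length-style formulas over a (level x size) count matrix."""
    ns = m.sum()
    if ns == 0:
        raise ValueError("empty matrix")
    n_lev, n_len = m.shape
    i = np.arange(1, n_lev + 1)[:, None]
    j = np.arange(1, n_len + 1)[None, :]
    ri = m.sum(axis=1)
    rj = m.sum(axis=0)
    p = m / ns
    mu_i = float((p.sum(axis=1) * np.arange(1, n_lev + 1)).sum())
    mu_j = float((p.sum(axis=0) * np.arange(1, n_len + 1)).sum())
    return {
        f"{prefix}short": float((rj / np.arange(1, n_len + 1) ** 2).sum() / ns),
        f"{prefix}long": float((rj * np.arange(1, n_len + 1) ** 2).sum() / ns),
        f"{prefix}low": float((ri / np.arange(1, n_lev + 1) ** 2).sum() / ns),
        f"{prefix}high": float((ri * np.arange(1, n_lev + 1) ** 2).sum() / ns),
        f"{prefix}short_low": float((m / (i ** 2 * j ** 2)).sum() / ns),
        f"{prefix}short_high": float((m * i ** 2 / j ** 2).sum() / ns),
        f"{prefix}long_low": float((m * j ** 2 / i ** 2).sum() / ns),
        f"{prefix}long_high": float((m * i ** 2 * j ** 2).sum() / ns),
        f"{prefix}gln": float((ri ** 2).sum() / ns),
        f"{prefix}glnn": float((ri ** 2).sum() / ns ** 2),
        f"{prefix}sn": float((rj ** 2).sum() / ns),
        f"{prefix}snn": float((rj ** 2).sum() / ns ** 2),
        f"{prefix}pct": float(ns / n_voxels),
        f"{prefix}glv": float((p * (i - mu_i) ** 2).sum()),
        f"{prefix}sv": float((p * (j - mu_j) ** 2).sum()),
        f"{prefix}entropy": float(-_xlog2(p).sum()),
    }


_RL_KEYMAP = {
    "short": "short_run_emphasis", "long": "long_run_emphasis",
    "low": "low_grey_level_run_emphasis", "high": "high_grey_level_run_emphasis",
    "short_low": "short_run_low_grey_level_emphasis",
    "short_high": "short_run_high_grey_level_emphasis",
    "long_low": "long_run_low_grey_level_emphasis",
    "long_high": "long_run_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity", "glnn": "grey_level_non_uniformity_normalized",
    "sn": "run_length_non_uniformity", "snn": "run_length_non_uniformity_normalized",
    "pct": "run_percentage", "glv": "grey_level_variance",
    "sv": "run_length_variance", "entropy": "run_entropy",
}

_SZ_KEYMAP = {
    "short": "small_zone_emphasis", "long": "large_zone_emphasis",
    "low": "low_grey_level_zone_emphasis", "high": "high_grey_level_zone_emphasis",
    "short_low": "small_zone_low_grey_level_emphasis",
    "short_high": "small_zone_high_grey_level_emphasis",
    "long_low": "large_zone_low_grey_level_emphasis",
    "long_high": "large_zone_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity", "glnn": "grey_level_non_uniformity_normalized",
    "sn": "zone_size_non_uniformity", "snn": "zone_size_non_uniformity_normalized",
    "pct": "zone_percentage", "glv": "grey_level_variance",
    "sv": "zone_size_variance", "entropy": "zone_size_entropy",
}

_DEP_KEYMAP = {
    "short": "low_dependence_emphasis", "long": "high_dependence_emphasis",
    "low": "low_grey_level_count_emphasis", "high": "high_grey_level_count_emphasis",
    "short_low": "low_dependence_low_grey_level_emphasis",
    "short_high": "low_dependence_high_grey_level_emphasis",
    "long_low": "high_dependence_low_grey_level_emphasis",
    "long_high": "high_dependence_high_grey_level_emphasis",
    "gln": "grey_level_non_uniformity", "glnn": "grey_level_non_uniformity_normalized",
    "sn": "dependence_count_non_uniformity",
    "snn": "dependence_count_non_uniformity_normalized",
    "pct": "dependence_count_percentage", "glv": "grey_level_variance",
    "sv": "dependence_count_variance", "entropy": "dependence_count_entropy",
}


def glrlm_features_single(m: np.ndarray, n_voxels: int) -> dict:
    raw = _rl_style_features(m, n_voxels, "")
    return {_RL_KEYMAP[k]: v for k, v in raw.items()}


def glszm_features_from_matrix(m: np.ndarray, n_voxels: int) -> dict:
    raw = _rl_style_features(m, n_voxels, "")
    return {_SZ_KEYMAP[k]: v for k, v in raw.items()}


def glszm_features(levels, n_levels) -> dict:
    n_voxels = int(np.isfinite(levels).sum())
    return glszm_features_from_matrix(matrices.glszm(levels, n_levels), n_voxels)


def ngldm_features_from_matrix(m: np.ndarray, n_voxels: int) -> dict:
    raw = _rl_style_features(m, n_voxels, "")
    out = {_DEP_KEYMAP[k]: v for k, v in raw.items()}
    p = m / m.sum()
    out["dependence_count_energy"] = float((p ** 2).sum())
    return out


def ngldm_features(levels, n_levels, alpha: float = 0.0) -> dict:
    n_voxels = int(np.isfinite(levels).sum())
    return ngldm_features_from_matrix(matrices.ngldm(levels, n_levels, alpha),
                                      n_voxels)


def ngtdm_features_from_vectors(s, n, p, n_levels) -> dict:
    np_tot = n.sum()
    if np_tot == 0:
        raise ValueError("no voxels with valid neighbourhoods")
    present = p > 0
    iv = np.arange(1, n_levels + 1, dtype=float)
    ip = iv[present]
    pp = p[present]
    sp = s[present]
    ngp = int(present.sum())

    coars_den = float((pp * sp).sum())
    coarseness = 1.0 / coars_den if coars_den > 0 else 1e6

    if ngp > 1:
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        pij = pp[:, None] * pp[None, :]
        contrast = float((pij * dif2).sum() / (ngp * (ngp - 1)) * (s.sum() / np_tot))
        bus_den = float(np.abs(ip[:, None] * pp[:, None] - ip[None, :] * pp[None, :]).sum())
        busyness = coars_den / bus_den if bus_den > 0 else 0.0
        num = np.abs(ip[:, None] - ip[None, :]) * (
            (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :])
            / (pp[:, None] + pp[None, :]))
        complexity = float(num.sum() / np_tot)
        s_sum = float(s.sum())
        strength = float(((pp[:, None] + pp[None, :]) * dif2).sum() / s_sum) \
            if s_sum > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0
    return {"coarseness": coarseness, "contrast": contrast, "busyness": busyness,
            "complexity": complexity, "strength": strength}


def ngtdm_features(levels, n_levels) -> dict:
    s, n, p = matrices.ngtdm(levels, n_levels)
    return ngtdm_features_from_vectors(s, n, p, n_levels)


def _average_directional(per_direction: list) -> dict:
    keys = per_direction[0].keys()
    return {k: float(np.mean([d[k] for d in per_direction])) for k in keys}


def glcm_features(levels, n_levels) -> dict:
    feats = []
    for d in matrices.DIRECTIONS_13:
        counts = matrices.glcm(levels, n_levels, d)
        if counts.sum() == 0:
            continue
        feats.append(glcm_features_single(counts))
    if not feats:
        raise ValueError("no valid voxel pairs in any direction")
    out = _average_directional(feats)
    assert set(out) == set(GLCM_FEATURES)
    return out


def glrlm_features(levels, n_levels) -> dict:
    n_voxels = int(np.isfinite(levels).sum())
    feats = [glrlm_features_single(matrices.glrlm(levels, n_levels, d), n_voxels)
             for d in matrices.DIRECTIONS_13]
    out = _average_directional(feats)
    assert set(out) == set(GLRLM_FEATURES)
    return out
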