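"""Assembly of the full 380-feature vector per patient."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..imaging import ImageVolume, RoiMask
from ..preprocess import PreprocessConfig, PreprocessedPatient, preprocess_patient
from .catalogue import FEATURE_NAMES, MODALITIES
from .intensity import histogram_features, integrated_intensity, intensity_statistics
from .shape import shape_features
from .texture import (glcm_features, glrlm_features, glszm_features,
                      ngldm_features, ngtdm_features)


def _crop_to_roi(levels: np.ndarray) -> np.ndarray:
    """Bounding-box crop around the finite voxels (texture cost saver)."""
    idx = np.argwhere(np.isfinite(levels))
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    return levels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]


def modality_features(masked: ImageVolume, discretized: ImageVolume,
                      mask: RoiMask, n_levels: int = 64) -> dict:
    """The 121 per-modality features (family-local names prefixed later)."""
    levels = _crop_to_roi(discretized.values)
    out = {}
    out.update({f"stat_{k}": v for k, v in intensity_statistics(masked).items()})
    out.update({f"hist_{k}": v for k, v in
                histogram_features(discretized, n_levels).items()})
    out["intensity_integrated_intensity"] = integrated_intensity(masked, mask)
    out.update({f"glcm_{k}": v for k, v in glcm_features(levels, n_levels).items()})
    out.update({f"glrlm_{k}": v for k, v in glrlm_features(levels, n_levels).items()})
    out.update({f"glszm_{k}": v for k, v in glszm_features(levels, n_levels).items()})
    out.update({f"ngtdm_{k}": v for k, v in ngtdm_features(levels, n_levels).items()})
    out.update({f"ngldm_{k}": v for k, v in ngldm_features(levels, n_levels).items()})
    return out


def extract_all(pre: PreprocessedPatient, n_levels: int = 64) -> pd.Series:
    """Full ordered 380-feature vector for one preprocessed patient."""
    missing = [m for m in MODALITIES if m not in pre.masked]
    if missing:
        raise ValueError(f"missing modalities: {missing}")
    vals = {f"shape_{k}": v for k, v in shape_features(pre.mask).items()}
    for mod in MODALITIES:
        mv = modality_features(pre.masked[mod], pre.discretized[mod],
                               pre.mask, n_levels)
        vals.update({f"{mod}_{k}": v for k, v in mv.items()})
    vec = pd.Series([vals[name] for name in FEATURE_NAMES], index=FEATURE_NAMES,
                    name=pre.patient_id, dtype=float)
    if not np.all(np.isfinite(vec.values)):
        bad = vec.index[~np.isfinite(vec.values)].tolist()
        raise ValueError(f"non-finite features for {pre.patient_id}: {bad}")
    return vec


def extract_cohort(records, config: PreprocessConfig = None) -> pd.DataFrame:
    """Feature table (rows = patients, 380 named columns) for a cohort."""
    config = config or PreprocessConfig()
    rows = [extract_all(preprocess_patient(r, config), config.n_grey_levels)
            for r in records]
    return pd.DataFrame(rows)
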