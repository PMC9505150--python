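"""The fixed 380-feature catalogue.

17 shape features computed once from the ROI mask, plus 121 features per
modality (CT, PET, BED): 18 intensity statistics, 23 intensity-histogram
features, 1 integrated intensity, 25 grey-level co-occurrence (GLCM),
16 run-length (GLRLM), 16 size-zone (GLSZM), 5 neighbourhood grey-tone
difference (NGTDM) and 17 grey-level dependence (NGLDM) features, following
the IBSI definitions of each family.  17 + 3 x 121 = 380.

The catalogue is data: ordering, families and modality scope live here, not
scattered through the extraction code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

MODALITIES = ("CT", "PET", "BED")

SHAPE_FEATURES = (
    "voxel_volume", "mesh_volume", "surface_area", "surface_to_volume_ratio",
    "compactness_1", "compactness_2", "spherical_disproportion", "sphericity",
    "asphericity", "max_3d_diameter", "major_axis_length", "minor_axis_length",
    "least_axis_length", "elongation", "flatness", "aabb_volume_density",
    "aabb_area_density",
)

STAT_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "interquartile_range", "range", "mean_absolute_deviation",
    "robust_mean_absolute_deviation", "median_absolute_deviation",
    "coefficient_of_variation", "quartile_coefficient_of_dispersion",
    "energy", "root_mean_square",
)

HISTOGRAM_FEATURES = (
    "mean", "variance", "skewness", "kurtosis", "median", "minimum", "p10",
    "p90", "maximum", "mode", "interquartile_range", "range",
    "mean_absolute_deviation", "robust_mean_absolute_deviation",
    "median_absolute_deviation", "coefficient_of_variation",
    "quartile_coefficient_of_dispersion", "entropy", "uniformity",
    "max_histogram_gradient", "max_histogram_gradient_level",
    "min_histogram_gradient", "min_histogram_gradient_level",
)

GLCM_FEATURES = (
    "joint_maximum", "joint_average", "joint_variance", "joint_entropy",
    "difference_average", "difference_variance", "difference_entropy",
    "sum_average", "sum_variance", "sum_entropy", "angular_second_moment",
    "contrast", "dissimilarity", "inverse_difference",
    "inverse_difference_normalized", "inverse_difference_moment",
    "inverse_difference_moment_normalized", "inverse_variance", "correlation",
    "autocorrelation", "cluster_tendency", "cluster_shade",
    "cluster_prominence", "information_correlation_1",
    "information_correlation_2",
)

GLRLM_FEATURES = (
    "short_run_emphasis", "long_run_emphasis", "low_grey_level_run_emphasis",
    "high_grey_level_run_emphasis", "short_run_low_grey_level_emphasis",
    "short_run_high_grey_level_emphasis", "long_run_low_grey_level_emphasis",
    "long_run_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "run_length_non_uniformity",
    "run_length_non_uniformity_normalized", "run_percentage",
    "grey_level_variance", "run_length_variance", "run_entropy",
)

GLSZM_FEATURES = (
    "small_zone_emphasis", "large_zone_emphasis", "low_grey_level_zone_emphasis",
    "high_grey_level_zone_emphasis", "small_zone_low_grey_level_emphasis",
    "small_zone_high_grey_level_emphasis", "large_zone_low_grey_level_emphasis",
    "large_zone_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "zone_size_non_uniformity",
    "zone_size_non_uniformity_normalized", "zone_percentage",
    "grey_level_variance", "zone_size_variance", "zone_size_entropy",
)

NGTDM_FEATURES = ("coarseness", "contrast", "busyness", "complexity", "strength")

NGLDM_FEATURES = (
    "low_dependence_emphasis", "high_dependence_emphasis",
    "low_grey_level_count_emphasis", "high_grey_level_count_emphasis",
    "low_dependence_low_grey_level_emphasis",
    "low_dependence_high_grey_level_emphasis",
    "high_dependence_low_grey_level_emphasis",
    "high_dependence_high_grey_level_emphasis", "grey_level_non_uniformity",
    "grey_level_non_uniformity_normalized", "dependence_count_non_uniformity",
    "dependence_count_non_uniformity_normalized", "dependence_count_percentage",
    "grey_level_variance", "dependence_count_variance",
    "dependence_count_entropy", "dependence_count_energy",
)

# per-modality family order
_MODALITY_FAMILIES = (
    ("stat", STAT_FEATURES),
    ("hist", HISTOGRAM_FEATURES),
    ("intensity", ("integrated_intensity",)),
    ("glcm", GLCM_FEATURES),
    ("glrlm", GLRLM_FEATURES),
    ("glszm", GLSZM_FEATURES),
    ("ngtdm", NGTDM_FEATURES),
    ("ngldm", NGLDM_FEATURES),
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str        # full column name, e.g. "BED_stat_variance"
    family: str      # shape | stat | hist | intensity | glcm | ...
    feature: str     # family-local name
    modality: str    # "" for shape, else CT | PET | BED


def build_catalogue() -> list:
    """The ordered list of all 380 feature descriptors."""
    cat = [FeatureDescriptor(f"shape_{f}", "shape", f, "") for f in SHAPE_FEATURES]
    for mod in MODALITIES:
        for family, feats in _MODALITY_FAMILIES:
            cat.extend(FeatureDescriptor(f"{mod}_{family}_{f}", family, f, mod)
                       for f in feats)
    names = [d.name for d in cat]
    assert len(names) == len(set(names)) == 380
    return cat


CATALOGUE = build_catalogue()
FEATURE_NAMES = tuple(d.name for d in CATALOGUE)


def write_catalogue_manifest(path):
    """Dump the catalogue as a JSON manifest (family, name, modality)."""
    with open(path, "w") as fh:
        json.dump([{"name": d.name, "family": d.family, "feature": d.feature,
                    "modality": d.modality} for d in CATALOGUE], fh, indent=1)
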