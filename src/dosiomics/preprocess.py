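"""Image-processing chain applied to every patient before feature extraction.

The pipeline order is fixed:

1. unit conversion — PET activity to body-weight SUV, physical dose to
   biologically effective dose (BED, linear-quadratic model);
2. rasterization of the GTV polygons into a binary mask on the native grid
   (crossing-number / even-odd test at voxel centres);
3. trilinear resampling of all volumes and of the (fractional) mask to
   isotropic 1 x 1 x 1 mm^3;
4. binarization of the resampled mask at 0.5;
5. rounding of CT values to integer HU;
6. ROI isolation — voxels outside the mask replaced by NaN;
7. fixed-bin-number discretization of the ROI intensities into 64 grey levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .imaging import ContourSet, DoseGrid, ImageVolume, RoiMask, Unit

log = logging.getLogger(__name__)

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain.

    alpha_beta_gy : tissue radiosensitivity ratio for the BED conversion;
        1.5 Gy is the conventional prostate value.
    target_spacing_mm : isotropic grid for resampling, (z, y, x) in mm.
    mask_binarization_threshold : fractional-mask cutoff after resampling,
        accounts for partial-volume voxels created by interpolation.
    n_grey_levels : fixed bin number for intensity discretization.
    pet_threshold_fraction : fraction of the SUV maximum used by the
        semi-automated PET segmentation.
    """

    alpha_beta_gy: float = 1.5
    target_spacing_mm: tuple = (1.0, 1.0, 1.0)
    mask_binarization_threshold: float = 0.5
    n_grey_levels: int = 64
    pet_threshold_fraction: float = 0.40

    def __post_init__(self):
        if self.alpha_beta_gy <= 0:
            raise ValueError("alpha_beta_gy must be positive")
        if not 0 < self.mask_binarization_threshold < 1:
            raise ValueError("mask_binarization_threshold must be in (0, 1)")
        if not 0 < self.pet_threshold_fraction < 1:
            raise ValueError("pet_threshold_fraction must be in (0, 1)")
        if self.n_grey_levels < 2:
            raise ValueError("n_grey_levels must be >= 2")


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def to_suv(pet: ImageVolume, body_weight_g: float, injected_activity_bq: float,
           delay_s: float, half_life_s: float) -> ImageVolume:
    """Convert activity concentration (Bq/mL) to body-weight SUV.

    SUV_v = c_v * w / A(t), with A(t) = A0 * 2**(-delay / half_life) the
    injected activity decay-corrected to scan time.  With 1 g/mL tissue
    density the result is dimensionless.
    """
    if pet.unit is not Unit.BQ_ML:
        raise ValueError(f"expected a Bq/mL volume, got {pet.unit}")
    if body_weight_g <= 0 or injected_activity_bq <= 0 or half_life_s <= 0:
        raise ValueError("body weight, injected activity and half-life must be positive")
    decayed = injected_activity_bq * 2.0 ** (-delay_s / half_life_s)
    return pet.with_values(pet.values * (body_weight_g / decayed), unit=Unit.SUV)


def to_bed(dose: DoseGrid, alpha_beta_gy: float = 1.5) -> ImageVolume:
    """Voxel-wise biologically effective dose under the linear-quadratic model.

    For a total dose D delivered in n equal fractions (d = D/n per fraction):
    BED = D * (1 + d / (alpha/beta)).  The prescription 35 Gy in 7 fractions
    at alpha/beta = 1.5 Gy gives 151.7 Gy.
    """
    if alpha_beta_gy <= 0:
        raise ValueError("alpha_beta_gy must be positive")
    d = dose.volume.values
    bed = d * (1.0 + (d / dose.n_fractions) / alpha_beta_gy)
    return dose.volume.with_values(bed, unit=Unit.BED_GY)


# ---------------------------------------------------------------------------
# contour rasterization
# ---------------------------------------------------------------------------

def _crossing_parity(px, py, polygon):
    """Vectorized even-odd test: horizontal +x ray from each (px, py).

    Edges are treated half-open in y (a vertex counts for the edge whose
    lower endpoint it is), which makes results deterministic for points in
    line with vertices.
    """
    x1 = polygon[:, 0]
    y1 = polygon[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    px = np.asarray(px, dtype=float)[..., None]
    py = np.asarray(py, dtype=float)[..., None]
    straddles = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at_y = x1 + (py - y1) * (x2 - x1) / np.where(y2 == y1, np.inf, y2 - y1)
    crossings = straddles & (px < x_at_y)
    return crossings.sum(axis=-1) % 2 == 1


def point_in_polygon(point, polygon) -> bool:
    """Crossing-number (even-odd) point-in-polygon test with a +x ray."""
    polygon = np.asarray(polygon, dtype=float)
    if polygon.shape[0] < 3:
        raise ValueError("polygon needs at least 3 vertices")
    area = 0.5 * abs(np.sum(polygon[:, 0] * np.roll(polygon[:, 1], -1)
                            - np.roll(polygon[:, 0], -1) * polygon[:, 1]))
    if area == 0:
        warnings.warn("degenerate zero-area polygon: no interior")
        return False
    return bool(_crossing_parity(point[0], point[1], polygon))


def rasterize(contours: ContourSet, reference: ImageVolume) -> RoiMask:
    """Binary mask on the reference grid: voxel centres inside the polygons.

    Each contour plane is assigned to the nearest reference slice (must be
    within half a slice spacing); several polygons on one slice combine by
    the even-odd rule, so nested contours carve holes.
    """
    nz, ny, nx = reference.shape
    oz, oy, ox = reference.origin_mm
    sz, sy, sx = reference.spacing_mm
    mask = np.zeros(reference.shape, dtype=bool)
    xs = ox + sx * np.arange(nx)
    ys = oy + sy * np.arange(ny)
    gx, gy = np.meshgrid(xs, ys)  # (ny, nx)
    bad = []
    for z_mm, poly in contours.slices:
        idx = (z_mm - oz) / sz
        k = int(round(idx))
        if k < 0 or k >= nz or abs(idx - k) > 0.5 + 1e-9:
            bad.append(z_mm)
            continue
        inside = _crossing_parity(gx, gy, poly)
        mask[k] ^= inside
    if bad:
        raise ValueError(f"contour planes outside the reference grid: z={bad}")
    return RoiMask(mask.astype(float), reference.spacing_mm, reference.origin_mm)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def _target_grid(volume_shape, spacing, origin, target):
    """New shape/origin so the output covers the input physical extent.

    The extent is taken edge-to-edge (centres +- half a voxel); the first
    output centre is placed half an output voxel inside the input's leading
    edge, so resampling an already-on-target grid is the identity.
    """
    shape_out, origin_out = [], []
    for n, s, o, ts in zip(volume_shape, spacing, origin, target):
        extent = n * s
        n_out = max(1, int(round(extent / ts)))
        if ts > extent:
            raise ValueError(f"target spacing {ts} mm exceeds the grid extent {extent} mm")
        shape_out.append(n_out)
        origin_out.append(o - s / 2.0 + ts / 2.0)
    return tuple(shape_out), tuple(origin_out)


def _resample_values(values, spacing, origin, shape_out, origin_out, target):
    coords = np.meshgrid(*[(oo + ts * np.arange(n) - o) / s
                           for n, s, o, oo, ts in
                           zip(shape_out, spacing, origin, origin_out, target)],
                         indexing="ij")
    return ndimage.map_coordinates(values, np.stack(coords), order=1, mode="nearest")


def resample_trilinear(volume: ImageVolume, target_spacing_mm=(1.0, 1.0, 1.0)) -> ImageVolume:
    """Resample onto an isotropic grid by trilinear interpolation.

    Output values are interpolated at the new voxel centres and therefore
    never overshoot the input range.
    """
    target = tuple(float(t) for t in np.broadcast_to(np.asarray(target_spacing_mm, float), (3,)))
    if any(t <= 0 for t in target):
        raise ValueError("target spacing must be positive")
    shape_out, origin_out = _target_grid(volume.shape, volume.spacing_mm,
                                         volume.origin_mm, target)
    out = _resample_values(volume.values, volume.spacing_mm, volume.origin_mm,
                           shape_out, origin_out, target)
    return ImageVolume(out, target, origin_out, volume.unit)


def resample_mask(mask: RoiMask, target_spacing_mm=(1.0, 1.0, 1.0),
                  threshold: float = 0.5) -> RoiMask:
    """Trilinear resampling of the mask as a real field, then binarization.

    Voxels whose interpolated occupancy is >= ``threshold`` survive; this is
    the partial-volume rule applied after interpolation.
    """
    target = tuple(float(t) for t in np.broadcast_to(np.asarray(target_spacing_mm, float), (3,)))
    shape_out, origin_out = _target_grid(mask.shape, mask.spacing_mm,
                                         mask.origin_mm, target)
    frac = _resample_values(mask.values.astype(float), mask.spacing_mm,
                            mask.origin_mm, shape_out, origin_out, target)
    return RoiMask((frac >= threshold).astype(float), target, origin_out)


def resample_to_frame(volume: ImageVolume, reference: ImageVolume) -> ImageVolume:
    """Trilinear resampling of ``volume`` onto the exact grid of ``reference``.

    Used to bring a dose or PET grid onto the CT frame when the stored grids
    differ; a no-op (copy) when the geometry already matches.
    """
    if volume.same_geometry(reference):
        return volume.with_values(volume.values.copy())
    out = _resample_values(volume.values, volume.spacing_mm, volume.origin_mm,
                           reference.shape, reference.origin_mm, reference.spacing_mm)
    return ImageVolume(out, reference.spacing_mm, reference.origin_mm, volume.unit)


# ---------------------------------------------------------------------------
# ROI isolation and discretization
# ---------------------------------------------------------------------------

def round_ct(ct: ImageVolume) -> ImageVolume:
    """Round CT values to the nearest integer HU, ties away from zero."""
    if ct.unit is not Unit.HU:
        raise ValueError("round_ct expects a HU volume")
    vals = ct.values
    rounded = np.sign(vals) * np.floor(np.abs(vals) + 0.5)
    rounded = np.where(np.isnan(vals), np.nan, rounded)
    return ct.with_values(rounded)


def apply_roi(volume: ImageVolume, mask: RoiMask) -> ImageVolume:
    """Keep voxels inside the mask; everything outside becomes NaN."""
    if not volume.same_geometry(mask):
        raise ValueError("volume and mask geometry differ")
    out = np.where(mask.binary, volume.values, np.nan)
    return volume.with_values(out)


def discretize_fbn(masked: ImageVolume, n_levels: int = 64) -> ImageVolume:
    """Fixed-bin-number discretization of the ROI intensities.

    g = min(floor(N * (x - min) / (max - min)) + 1, N) over the non-NaN
    voxels, so levels run 1..N; a constant ROI maps entirely to level 1.
    The mapping is invariant to affine rescaling of the ROI intensities.
    """
    vals = masked.values
    inside = np.isfinite(vals)
    if not inside.any():
        raise ValueError("empty ROI: nothing to discretize")
    vmin = vals[inside].min()
    vmax = vals[inside].max()
    out = np.full(vals.shape, np.nan)
    if vmax == vmin:
        out[inside] = 1.0
    else:
        g = np.floor(n_levels * (vals[inside] - vmin) / (vmax - vmin)) + 1
        out[inside] = np.minimum(g, n_levels)
    return masked.with_values(out, unit=Unit.GREY_LEVEL)


def segment_pet_fixed_threshold(pet_suv: ImageVolume, search_mask: RoiMask,
                                fraction: float = 0.40) -> RoiMask:
    """Semi-automated PET segmentation: fixed fraction of the regional maximum.

    Keeps voxels in the search region with SUV >= fraction * max, restricted
    to the 26-connected component containing the maximum.
    """
    region = search_mask.binary
    if not region.any():
        raise ValueError("empty search region")
    vals = np.where(region, pet_suv.values, -np.inf)
    vmax = vals.max()
    region_vals = pet_suv.values[region]
    if np.all(region_vals == region_vals.flat[0]):
        warnings.warn("search region is constant; returning the whole region")
        return RoiMask(region.astype(float), search_mask.spacing_mm, search_mask.origin_mm)
    above = vals >= fraction * vmax
    labels, _ = ndimage.label(above, structure=_CONN26)
    peak = np.unravel_index(np.argmax(vals), vals.shape)
    keep = labels == labels[peak]
    return RoiMask(keep.astype(float), search_mask.spacing_mm, search_mask.origin_mm)


# ---------------------------------------------------------------------------
# full per-patient chain
# ---------------------------------------------------------------------------

@dataclass
class PreprocessedPatient:
    """Per-modality masked + discretized volumes on the isotropic grid."""

    patient_id: str
    mask: RoiMask
    masked: dict = field(default_factory=dict)       # modality -> ImageVolume (NaN outside ROI)
    discretized: dict = field(default_factory=dict)  # modality -> ImageVolume (grey levels)


def preprocess_patient(record, config: PreprocessConfig = None) -> PreprocessedPatient:
    """Run the full chain on one patient record.

    Produces masked and discretized CT, PET-SUV and BED volumes on the
    isotropic grid, plus the binarized ROI mask, ready for feature extraction.
    """
    config = config or PreprocessConfig()
    rp = record.radiopharm
    suv = to_suv(record.pet, rp.body_weight_g, rp.injected_activity_bq,
                 rp.injection_to_scan_s, rp.half_life_s)
    bed = to_bed(record.dose, config.alpha_beta_gy)
    # bring every grid onto the CT frame before the isotropic resampling
    suv = resample_to_frame(suv, record.ct)
    bed = resample_to_frame(bed, record.ct)

    native_mask = rasterize(record.gtv, record.ct)
    mask = resample_mask(native_mask, config.target_spacing_mm,
                         config.mask_binarization_threshold)
    ct = round_ct(resample_trilinear(record.ct, config.target_spacing_mm))
    suv = resample_trilinear(suv, config.target_spacing_mm)
    bed = resample_trilinear(bed, config.target_spacing_mm)

    out = PreprocessedPatient(record.patient_id, mask)
    for name, vol in (("CT", ct), ("PET", suv), ("BED", bed)):
        roi = apply_roi(vol, mask)
        out.masked[name] = roi
        out.discretized[name] = discretize_fbn(roi, config.n_grey_levels)
        n = int(np.isfinite(roi.values).sum())
        log.debug("%s %s: %d ROI voxels, range [%g, %g]", record.patient_id,
                  name, n, np.nanmin(roi.values), np.nanmax(roi.values))
    return out
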