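"""Synthetic phantom cohorts.

Emulates the study conditions of a partial-prostate re-irradiation cohort:
a small cohort (default 43 patients, ~30% event prevalence), a GTV of a few
cm^3 delineated as per-slice polygons, a choline-PET uptake focus, and an
SBRT-like dose distribution (35 Gy in 7 fractions: a high plateau inside the
target with a steep sigmoid fall-off).

The outcome is planted in the dose texture: each patient's local-failure
probability follows a logistic model on the standardized within-GTV BED
variance, so a leakage-free pipeline can recover the signal while a permuted
or null cohort cannot.  This driver is a modelling choice of the generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .imaging import (ContourSet, DoseGrid, ImageVolume, PatientRecord,
                      RadiopharmaceuticalInfo, Unit)
from .preprocess import rasterize, to_bed

EVENT_HORIZON_MONTHS = 36.0


@dataclass
class PhantomParams:
    """Cohort-level generator settings.

    gtv_radius_mm is (mean, jitter): each semi-axis of a patient's ellipsoidal
    GTV is drawn from N(mean, jitter^2), clipped to at least 3 mm.
    dose_heterogeneity (Gy) scales the within-GTV BED texture spread; the
    per-patient heterogeneity amplitude varies uniformly in [0.4, 1.6] times
    this value, which is what spreads the planted BED-variance signal across
    the cohort.  effect_size is the log-odds increase in 3-year local failure
    per standard deviation of within-GTV BED variance.
    """

    n_patients: int = 43
    prevalence: float = 0.302
    grid_shape: tuple = (32, 32, 32)
    spacing_mm: tuple = (2.0, 2.0, 2.0)
    gtv_radius_mm: tuple = (8.0, 1.0)
    dose_prescription_gy: float = 35.0
    n_fractions: int = 7
    dose_heterogeneity: float = 1.5
    effect_size: float = 2.0
    penumbra_mm: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.dose_heterogeneity < 0:
            raise ValueError("dose_heterogeneity must be non-negative")


def _smooth_noise(rng, shape, sigma_vox=1.0):
    """Correlated zero-mean unit-variance Gaussian field."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma_vox)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def _ellipsoid_contours(center_zyx, semi_axes_zyx, spacing_z, origin_z, n_slices,
                        rng, n_vertices=24, radial_jitter=0.02) -> ContourSet:
    """Per-slice polygons approximating a (slightly jittered) ellipsoid."""
    cz, cy, cx = center_zyx
    az, ay, ax = semi_axes_zyx
    slices = []
    phases = rng.uniform(0, 2 * np.pi, size=3)
    for k in range(n_slices):
        z = origin_z + k * spacing_z
        u = (z - cz) / az
        if abs(u) >= 0.999:
            continue
        scale = np.sqrt(1.0 - u * u)
        ry, rx = ay * scale, ax * scale
        if min(ry, rx) < 0.3 * min(spacing_z, 1.0):
            continue
        phi = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
        # smooth deterministic per-slice wobble of the radial profile
        wob = 1.0 + radial_jitter * (np.sin(2 * phi + phases[0])
                                     + 0.5 * np.sin(3 * phi + phases[1] + 0.1 * k))
        xs = cx + rx * wob * np.cos(phi)
        ys = cy + ry * wob * np.sin(phi)
        slices.append((z, np.column_stack([xs, ys])))
    if len(slices) < 2:
        raise ValueError("GTV too small for the slice spacing")
    return ContourSet("GTV", slices)


def _ellipsoid_radius(grid_axes, center, semi_axes):
    """Normalized ellipsoidal radius (1 on the surface) on the whole grid."""
    zz, yy, xx = np.meshgrid(*grid_axes, indexing="ij")
    return np.sqrt(((zz - center[0]) / semi_axes[0]) ** 2
                   + ((yy - center[1]) / semi_axes[1]) ** 2
                   + ((xx - center[2]) / semi_axes[2]) ** 2)


def generate_patient(params: PhantomParams, rng, patient_id: str = "P000",
                     event: bool = False, time_months: float = 60.0):
    """Generate one synthetic patient (deterministic given the rng state).

    Returns ``(record, bed_variance)`` where ``bed_variance`` is the
    within-GTV variance of the biologically effective dose on the native
    grid — the latent driver used by :func:`generate_cohort` to plant the
    outcome signal.
    """
    shape = tuple(params.grid_shape)
    spacing = tuple(float(s) for s in params.spacing_mm)
    extent = [n * s for n, s in zip(shape, spacing)]
    origin = (0.0, 0.0, 0.0)
    axes = [o + s * np.arange(n) for o, s, n in zip(origin, spacing, shape)]

    mean_r, jitter_r = params.gtv_radius_mm
    semi = np.clip(rng.normal(mean_r, jitter_r, size=3), 3.0, None)
    center = np.array([e / 2 for e in extent]) + rng.uniform(-2.0, 2.0, size=3)
    margin = 2.0 * max(spacing) + params.penumbra_mm
    for c, a, e in zip(center, semi, extent):
        if c - a - margin < 0 or c + a + margin > e - max(spacing):
            raise ValueError("GTV (plus penumbra margin) does not fit inside the grid")

    rho = _ellipsoid_radius(axes, center, semi)
    r_eff = float(np.mean(semi))
    surf_dist = (rho - 1.0) * r_eff  # approx. signed distance to GTV surface, mm

    # CT: soft tissue ~40 HU + correlated noise
    ct_vals = 40.0 + 8.0 * _smooth_noise(rng, shape, 1.0)
    ct = ImageVolume(ct_vals, spacing, origin, Unit.HU)

    # PET: background activity + ellipsoidal uptake focus, peak >= 4x background
    background = 1000.0
    peak = background * rng.uniform(5.0, 8.0)
    uptake = background + (peak - background) * np.exp(-2.0 * rho ** 2)
    pet_vals = np.clip(uptake * (1.0 + 0.05 * _smooth_noise(rng, shape, 1.0)), 0, None)
    pet = ImageVolume(pet_vals, spacing, origin, Unit.BQ_ML)
    radiopharm = RadiopharmaceuticalInfo(
        injected_activity_bq=float(rng.uniform(3.0e8, 4.5e8)),
        injection_to_scan_s=300.0,
        half_life_s=1223.4,  # 11C
        body_weight_g=float(rng.uniform(6.5e4, 9.5e4)),
    )

    # dose: exact prescription plateau covering the GTV (plus a small margin
    # absorbing the polygonal wobble of the contours), sigmoid fall-off outside
    plateau_mm = 0.5
    s_out = surf_dist - plateau_mm
    fall = np.where(s_out <= 0.0, 1.0,
                    2.0 / (1.0 + np.exp(s_out / params.penumbra_mm)))
    dose_vals = params.dose_prescription_gy * fall
    if params.dose_heterogeneity > 0:
        amp = params.dose_heterogeneity * rng.uniform(0.4, 1.6)
        texture = _smooth_noise(rng, shape, 1.2)
        dose_vals = dose_vals + amp * texture * (s_out <= 0.0)
    else:
        rng.uniform(0.4, 1.6)          # keep the stream aligned
        _smooth_noise(rng, shape, 1.2)
    dose_vals = np.clip(dose_vals, 0.0, None)
    dose = DoseGrid(ImageVolume(dose_vals, spacing, origin, Unit.GY), params.n_fractions)

    gtv = _ellipsoid_contours(center, semi, spacing[0], origin[0], shape[0], rng)

    record = PatientRecord(patient_id, ct, pet, radiopharm, dose, gtv,
                           event=event, time_months=time_months)
    mask = rasterize(gtv, ct).binary
    bed = to_bed(dose).values
    bed_var = float(bed[mask].var()) if mask.any() else 0.0
    return record, bed_var


def _calibrate_intercept(z, effect_size, prevalence):
    """Bisection on the intercept so mean event probability hits prevalence."""
    def gap(a):
        return np.mean(1.0 / (1.0 + np.exp(-(a + effect_size * z)))) - prevalence

    lo, hi = -30.0, 30.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError("intercept calibration failed to bracket the prevalence")
    return optimize.brentq(gap, lo, hi, xtol=1e-10)


def generate_cohort(params: PhantomParams):
    """Generate a full cohort with the planted logistic outcome.

    logit P(event) = intercept + effect_size * z, with z the cohort-
    standardized within-GTV BED variance; the intercept is calibrated by
    bisection so the expected prevalence matches ``params.prevalence``.
    Event times are uniform on (6, 35) months (inside the 36-month horizon);
    event-free follow-up is uniform on (12, 102) months.
    """
    if params.n_patients < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(params.seed)
    records, bed_vars = [], []
    for i in range(params.n_patients):
        rec, bv = generate_patient(params, rng, patient_id=f"P{i:04d}")
        records.append(rec)
        bed_vars.append(bv)
    z = np.asarray(bed_vars)
    sd = z.std()
    z = (z - z.mean()) / sd if sd > 0 else np.zeros_like(z)
    intercept = _calibrate_intercept(z, params.effect_size, params.prevalence)
    p = 1.0 / (1.0 + np.exp(-(intercept + params.effect_size * z)))
    events = rng.uniform(size=params.n_patients) < p
    for rec, ev in zip(records, events):
        rec.event = bool(ev)
        rec.time_months = float(rng.uniform(6.0, 35.0) if ev
                                else rng.uniform(12.0, 102.0))
    return records
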