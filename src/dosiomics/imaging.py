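"""Core volumetric data model.

Conventions used throughout the package:

* Arrays are indexed ``[z, y, x]``; the ``spacing_mm`` and ``origin_mm``
  triples are ordered like the array axes, i.e. ``(z, y, x)``.
* The centre of voxel ``(0, 0, 0)`` sits at ``origin_mm``; indices are
  0-based, so the centre of voxel ``(i, j, k)`` is at
  ``origin_mm + (i, j, k) * spacing_mm`` in patient coordinates (mm).
* Orientation is the axial identity; oblique direction cosines are rejected.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace

import numpy as np


class Unit(str, enum.Enum):
    """Physical interpretation of the voxel values of an :class:`ImageVolume`."""

    HU = "HU"
    BQ_ML = "BQ_ML"
    SUV = "SUV"
    GY = "GY"
    BED_GY = "BED_GY"
    GREY_LEVEL = "GREY_LEVEL"


_IDENTITY = np.eye(3)


def _as_triple(v, name):
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a length-3 sequence, got shape {arr.shape}")
    return tuple(float(x) for x in arr)


@dataclass
class ImageVolume:
    """A 3D scalar grid with geometry metadata and a declared intensity unit.

    ``values`` may contain NaN only where voxels have been explicitly masked
    out (see :func:`dosiomics.preprocess.apply_roi`); readers and generators
    always produce finite volumes.
    """

    values: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)
    unit: Unit = Unit.HU
    direction: np.ndarray = field(default_factory=lambda: _IDENTITY.copy())

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing_mm}")
        self.unit = Unit(self.unit)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.direction.shape != (3, 3) or not np.allclose(self.direction, _IDENTITY):
            raise ValueError("only axial identity orientation is supported")

    @property
    def shape(self):
        return self.values.shape

    def with_values(self, values, unit=None) -> "ImageVolume":
        """Same geometry, new values (and optionally a new unit)."""
        return replace(self, values=np.asarray(values, dtype=float),
                       unit=self.unit if unit is None else Unit(unit))

    def same_geometry(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))

    def voxel_centers_mm(self):
        """Patient-coordinate (z, y, x) centres, three 1D axes arrays."""
        return tuple(o + s * np.arange(n)
                     for o, s, n in zip(self.origin_mm, self.spacing_mm, self.shape))


@dataclass
class RoiMask:
    """Binary (or, transiently, fractional) region-of-interest mask.

    Shares the geometry conventions of :class:`ImageVolume`.
    """

    values: np.ndarray
    spacing_mm: tuple
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D")
        self.spacing_mm = _as_triple(self.spacing_mm, "spacing_mm")
        self.origin_mm = _as_triple(self.origin_mm, "origin_mm")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing must be strictly positive")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("mask values must lie in [0, 1]")

    @property
    def shape(self):
        return self.values.shape

    @property
    def binary(self) -> np.ndarray:
        return self.values >= 0.5 if self.values.dtype != bool else self.values

    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.values >= 0.5))

    def same_geometry(self, other) -> bool:
        return (self.shape == other.shape
                and np.allclose(self.spacing_mm, other.spacing_mm)
                and np.allclose(self.origin_mm, other.origin_mm))


@dataclass
class ContourSet:
    """Per-slice closed planar polygons in patient coordinates for one ROI.

    ``slices`` is a list of ``(z_mm, vertices)`` pairs where ``vertices`` is an
    ``(n, 2)`` array of ``(x_mm, y_mm)`` points; the polygon is implicitly
    closed (last vertex connects back to the first).  A slice z may appear more
    than once; overlapping polygons on one slice combine by the even-odd rule.
    """

    roi_name: str
    slices: list

    def __post_init__(self):
        cleaned = []
        for z, poly in self.slices:
            poly = np.asarray(poly, dtype=float)
            if poly.ndim != 2 or poly.shape[1] != 2:
                raise ValueError("each polygon must be an (n, 2) array of (x, y)")
            if poly.shape[0] < 3:
                raise ValueError("polygons need at least 3 vertices")
            cleaned.append((float(z), poly))
        self.slices = cleaned

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class DoseGrid:
    """A physical dose distribution plus the fractionation it was delivered in."""

    volume: ImageVolume
    n_fractions: int

    def __post_init__(self):
        if self.volume.unit is not Unit.GY:
            raise ValueError(f"dose grid must carry unit GY, got {self.volume.unit}")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if np.nanmin(self.volume.values) < 0:
            raise ValueError("dose values must be non-negative")


@dataclass
class RadiopharmaceuticalInfo:
    """PET injection metadata needed for the SUV conversion."""

    injected_activity_bq: float
    injection_to_scan_s: float
    half_life_s: float
    body_weight_g: float

    def __post_init__(self):
        for name in ("injected_activity_bq", "half_life_s", "body_weight_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.injection_to_scan_s < 0:
            raise ValueError("injection_to_scan_s must be non-negative")


@dataclass
class PatientRecord:
    """One patient: imaging, dose, target contours and the clinical endpoint."""

    patient_id: str
    ct: ImageVolume
    pet: ImageVolume
    radiopharm: RadiopharmaceuticalInfo
    dose: DoseGrid
    gtv: ContourSet
    event: bool
    time_months: float

    def __post_init__(self):
        if self.time_months <= 0:
            raise ValueError("time_months must be positive")
        if self.ct.unit is not Unit.HU:
            raise ValueError("ct must be in HU")
        if self.pet.unit is not Unit.BQ_ML:
            warnings.warn("pet volume is not in raw activity concentration (Bq/mL)")
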