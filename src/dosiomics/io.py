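"""Reading and writing patient data.

Two on-disk layouts are supported:

* the *portable container*: one directory per patient holding raw
  little-endian float32 volumes (``ct.f32``, ``pet.f32``, ``dose.f32``), a
  JSON sidecar ``meta.json`` (shapes, spacing, origin, units,
  radiopharmaceutical data, fractionation, outcome) and ``gtv.json`` with the
  per-slice contour polygons;
* DICOM series (CT, PT, RTDOSE, RTSTRUCT), handled in
  :mod:`dosiomics.dicom_io`.

``read_patient`` auto-detects the layout.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

import numpy as np

from .imaging import (ContourSet, DoseGrid, ImageVolume, PatientRecord,
                      RadiopharmaceuticalInfo, Unit)

log = logging.getLogger(__name__)


class MissingSeriesError(FileNotFoundError):
    """A required series/file (CT, PT, RTDOSE, RTSTRUCT) is absent."""


def _write_raw(path: Path, volume: ImageVolume):
    volume.values.astype("<f4").tofile(path)


def _volume_meta(volume: ImageVolume):
    return {"shape": list(volume.shape), "spacing_mm": list(volume.spacing_mm),
            "origin_mm": list(volume.origin_mm), "unit": volume.unit.value}


def _read_raw(path: Path, meta) -> ImageVolume:
    values = np.fromfile(path, dtype="<f4").astype(float).reshape(meta["shape"])
    return ImageVolume(values, tuple(meta["spacing_mm"]), tuple(meta["origin_mm"]),
                       Unit(meta["unit"]))


def write_patient_portable(record: PatientRecord, directory) -> list:
    """Serialize one patient into the portable container; returns file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for name, vol in (("ct", record.ct), ("pet", record.pet), ("dose", record.dose.volume)):
        p = directory / f"{name}.f32"
        _write_raw(p, vol)
        files.append(p)
    meta = {
        "patient_id": record.patient_id,
        "ct": _volume_meta(record.ct),
        "pet": _volume_meta(record.pet),
        "dose": _volume_meta(record.dose.volume),
        "n_fractions": record.dose.n_fractions,
        "radiopharm": {
            "injected_activity_bq": record.radiopharm.injected_activity_bq,
            "injection_to_scan_s": record.radiopharm.injection_to_scan_s,
            "half_life_s": record.radiopharm.half_life_s,
            "body_weight_g": record.radiopharm.body_weight_g,
        },
        "outcome": {"event": bool(record.event), "time_months": record.time_months},
    }
    mp = directory / "meta.json"
    mp.write_text(json.dumps(meta, indent=1))
    files.append(mp)
    gtv = {"roi_name": record.gtv.roi_name,
           "slices": [{"z_mm": z, "xy_mm": poly.tolist()} for z, poly in record.gtv.slices]}
    gp = directory / "gtv.json"
    gp.write_text(json.dumps(gtv))
    files.append(gp)
    log.info("wrote portable container for %s to %s", record.patient_id, directory)
    return files


def _read_portable(directory: Path) -> PatientRecord:
    meta = json.loads((directory / "meta.json").read_text())
    for name in ("ct", "pet", "dose"):
        if not (directory / f"{name}.f32").exists():
            raise MissingSeriesError(f"{name} volume absent in {directory}")
    gtv_path = directory / "gtv.json"
    if not gtv_path.exists():
        raise MissingSeriesError(f"structure set absent in {directory}")
    gtv_raw = json.loads(gtv_path.read_text())
    gtv = ContourSet(gtv_raw["roi_name"],
                     [(s["z_mm"], np.asarray(s["xy_mm"])) for s in gtv_raw["slices"]])
    rp = RadiopharmaceuticalInfo(**meta["radiopharm"])
    return PatientRecord(
        patient_id=meta["patient_id"],
        ct=_read_raw(directory / "ct.f32", meta["ct"]),
        pet=_read_raw(directory / "pet.f32", meta["pet"]),
        radiopharm=rp,
        dose=DoseGrid(_read_raw(directory / "dose.f32", meta["dose"]), meta["n_fractions"]),
        gtv=gtv,
        event=meta["outcome"]["event"],
        time_months=meta["outcome"]["time_months"],
    )


def read_patient(directory, roi_name: str | None = None) -> PatientRecord:
    """Load one patient from a portable container or a DICOM directory.

    ``roi_name`` selects the GTV ROI when reading DICOM RTSTRUCT (required
    there, ignored for the portable container which stores a single ROI).
    """
    directory = Path(directory)
    if (directory / "meta.json").exists():
        return _read_portable(directory)
    if any(directory.glob("*.dcm")):
        from . import dicom_io
        return dicom_io.read_patient_dicom(directory, roi_name=roi_name)
    raise MissingSeriesError(f"no portable container or DICOM series found in {directory}")


def write_cohort(cohort, directory, format: str = "portable"):
    """Write a cohort (one sub-directory per patient) plus a manifest CSV.

    Returns the manifest: a list of ``(patient_id, path, event, time_months)``
    rows. An empty cohort produces an empty manifest and no files.
    """
    if format not in ("portable", "dicom"):
        raise ValueError(f"unsupported format {format!r}")
    directory = Path(directory)
    manifest = []
    for record in cohort:
        pdir = directory / record.patient_id
        if format == "portable":
            write_patient_portable(record, pdir)
        else:
            from . import dicom_io
            dicom_io.write_patient_dicom(record, pdir)
        manifest.append((record.patient_id, str(pdir), bool(record.event),
                         float(record.time_months)))
    if manifest:
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["patient_id", "path", "event", "time_months"])
            w.writerows(manifest)
    return manifest


def read_cohort(directory) -> list:
    """Read every patient listed in a cohort manifest."""
    directory = Path(directory)
    records = []
    with open(directory / "manifest.csv") as fh:
        for row in csv.DictReader(fh):
            records.append(read_patient(row["path"]))
    return records
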