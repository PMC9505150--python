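"""Minimal DICOM writer/reader for CT, PT, RTDOSE and RTSTRUCT.

Covers the mandatory geometry/scaling tags needed to round-trip the package's
:class:`~dosiomics.imaging.PatientRecord` objects; axial identity orientation
only, one ROI per structure set.  CT is stored as int16 with rescale
slope/intercept, PT as uint16 with a per-series rescale slope (so the
round-trip is exact only to ~1e-4 relative), RTDOSE as uint32 with
DoseGridScaling.  The binary clinical outcome has no DICOM home and travels
in an ``outcome.json`` sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .imaging import (ContourSet, DoseGrid, ImageVolume, PatientRecord,
                      RadiopharmaceuticalInfo, Unit)
from .io import MissingSeriesError

_CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
_PT_SOP = "1.2.840.10008.5.1.4.1.1.128"
_RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"
_RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"


def _base_dataset(sop_class, patient_id):
    meta = pydicom.dataset.FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = patient_id
    ds.PatientName = patient_id
    ds.Modality = {_CT_SOP: "CT", _PT_SOP: "PT", _RTDOSE_SOP: "RTDOSE",
                   _RTSTRUCT_SOP: "RTSTRUCT"}[sop_class]
    return ds


def _write_slice_series(volume: ImageVolume, directory: Path, sop_class,
                        patient_id, prefix, rescale):
    """One file per axial slice; returns the series UID."""
    series_uid = generate_uid()
    nz = volume.shape[0]
    sz, sy, sx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    for k in range(nz):
        ds = _base_dataset(sop_class, patient_id)
        ds.SeriesInstanceUID = series_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [ox, oy, oz + k * sz]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sy, sx]
        ds.SliceThickness = sz
        ds.Rows, ds.Columns = volume.shape[1], volume.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        slope, intercept, signed = rescale
        ds.PixelRepresentation = 1 if signed else 0
        ds.RescaleSlope = slope
        ds.RescaleIntercept = intercept
        raw = (volume.values[k] - intercept) / slope
        dtype = np.int16 if signed else np.uint16
        ds.PixelData = np.round(raw).astype(dtype).tobytes()
        ds.save_as(directory / f"{prefix}_{k:03d}.dcm", enforce_file_format=True)
    return series_uid


def write_patient_dicom(record: PatientRecord, directory) -> list:
    """Write CT + PT series, RTDOSE, RTSTRUCT and the outcome sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    pid = record.patient_id

    _write_slice_series(record.ct, directory, _CT_SOP, pid, "ct",
                        rescale=(1.0, -1024.0, True))
    pet_max = float(record.pet.values.max()) or 1.0
    pet_slope = pet_max / 60000.0
    _write_slice_series(record.pet, directory, _PT_SOP, pid, "pt",
                        rescale=(pet_slope, 0.0, False))
    # attach radiopharmaceutical info to the first PT slice
    first_pt = sorted(directory.glob("pt_*.dcm"))[0]
    ds = pydicom.dcmread(first_pt)
    rp = Dataset()
    rp.RadionuclideTotalDose = record.radiopharm.injected_activity_bq
    rp.RadionuclideHalfLife = record.radiopharm.half_life_s
    rp.RadiopharmaceuticalStartTime = "000000"
    ds.RadiopharmaceuticalInformationSequence = [rp]
    ds.PatientWeight = record.radiopharm.body_weight_g / 1000.0
    ds.add_new(0x00091001, "DS", str(record.radiopharm.injection_to_scan_s))
    ds.save_as(first_pt, enforce_file_format=True)

    # RTDOSE: single multi-frame file
    dose_vol = record.dose.volume
    ds = _base_dataset(_RTDOSE_SOP, pid)
    ds.SeriesInstanceUID = generate_uid()
    sz, sy, sx = dose_vol.spacing_mm
    oz, oy, ox = dose_vol.origin_mm
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [sy, sx]
    ds.GridFrameOffsetVector = [k * sz for k in range(dose_vol.shape[0])]
    ds.NumberOfFrames = dose_vol.shape[0]
    ds.Rows, ds.Columns = dose_vol.shape[1], dose_vol.shape[2]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    scaling = float(dose_vol.values.max()) / (2 ** 32 - 1) or 1e-9
    ds.DoseGridScaling = scaling
    ds.add_new(0x300B1001, "IS", str(record.dose.n_fractions))  # private: fractions
    ds.PixelData = np.round(dose_vol.values / scaling).astype(np.uint32).tobytes()
    ds.save_as(directory / "rtdose.dcm", enforce_file_format=True)

    # RTSTRUCT with the single GTV ROI
    ds = _base_dataset(_RTSTRUCT_SOP, pid)
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = "GTV set"
    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = record.gtv.roi_name
    ds.StructureSetROISequence = [roi]
    rc = Dataset()
    rc.ReferencedROINumber = 1
    contours = []
    for z, poly in record.gtv.slices:
        c = Dataset()
        c.ContourGeometricType = "CLOSED_PLANAR"
        c.NumberOfContourPoints = len(poly)
        data = []
        for x, y in poly:
            data.extend([float(x), float(y), float(z)])
        c.ContourData = data
        contours.append(c)
    rc.ContourSequence = contours
    ds.ROIContourSequence = [rc]
    ds.save_as(directory / "rtstruct.dcm", enforce_file_format=True)

    (directory / "outcome.json").write_text(json.dumps(
        {"event": bool(record.event), "time_months": record.time_months}))
    return sorted(p.name for p in directory.iterdir())


def _read_slice_series(paths) -> tuple:
    slices = sorted((pydicom.dcmread(p) for p in paths),
                    key=lambda d: float(d.ImagePositionPatient[2]))
    first = slices[0]
    if [float(v) for v in first.ImageOrientationPatient] != [1, 0, 0, 0, 1, 0]:
        raise ValueError("only axial identity orientation is supported")
    zs = [float(s.ImagePositionPatient[2]) for s in slices]
    dz = np.diff(zs)
    if len(dz) and not np.allclose(dz, dz[0], atol=1e-6):
        raise ValueError("inconsistent slice spacing")
    sy, sx = (float(v) for v in first.PixelSpacing)
    sz = float(dz[0]) if len(dz) else float(getattr(first, "SliceThickness", 1.0))
    vol = np.stack([s.pixel_array * float(getattr(s, "RescaleSlope", 1.0))
                    + float(getattr(s, "RescaleIntercept", 0.0)) for s in slices])
    origin = (zs[0], float(first.ImagePositionPatient[1]),
              float(first.ImagePositionPatient[0]))
    return vol, (sz, sy, sx), origin, first


def read_patient_dicom(directory, roi_name: str | None = None) -> PatientRecord:
    """Assemble a PatientRecord from one CT series, one PT series, one
    RTDOSE and one RTSTRUCT; ``roi_name`` selects the GTV ROI."""
    directory = Path(directory)
    groups = {"CT": [], "PT": [], "RTDOSE": [], "RTSTRUCT": []}
    for p in sorted(directory.glob("*.dcm")):
        ds = pydicom.dcmread(p, stop_before_pixels=True)
        groups.setdefault(ds.Modality, []).append(p)
    for mod in ("CT", "PT"):
        if not groups[mod]:
            raise MissingSeriesError(f"{mod} series absent in {directory}")
    if not groups["RTDOSE"]:
        raise MissingSeriesError(f"RTDOSE absent in {directory}")
    if not groups["RTSTRUCT"]:
        raise MissingSeriesError(f"structure set absent in {directory}")

    ct_vals, ct_sp, ct_or, ct_first = _read_slice_series(groups["CT"])
    ct = ImageVolume(ct_vals, ct_sp, ct_or, Unit.HU)

    pt_vals, pt_sp, pt_or, pt_first = _read_slice_series(groups["PT"])
    pet = ImageVolume(pt_vals, pt_sp, pt_or, Unit.BQ_ML)
    pt_meta = pydicom.dcmread(sorted(groups["PT"])[0])
    rp_seq = pt_meta.RadiopharmaceuticalInformationSequence[0]
    radiopharm = RadiopharmaceuticalInfo(
        injected_activity_bq=float(rp_seq.RadionuclideTotalDose),
        injection_to_scan_s=float(pt_meta[0x00091001].value),
        half_life_s=float(rp_seq.RadionuclideHalfLife),
        body_weight_g=float(pt_meta.PatientWeight) * 1000.0,
    )

    dd = pydicom.dcmread(groups["RTDOSE"][0])
    offsets = [float(v) for v in dd.GridFrameOffsetVector]
    sz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    sy, sx = (float(v) for v in dd.PixelSpacing)
    vals = dd.pixel_array.astype(float) * float(dd.DoseGridScaling)
    origin = (float(dd.ImagePositionPatient[2]) + offsets[0],
              float(dd.ImagePositionPatient[1]), float(dd.ImagePositionPatient[0]))
    n_fractions = int(dd[0x300B1001].value) if 0x300B1001 in dd else 1
    dose = DoseGrid(ImageVolume(vals, (sz, sy, sx), origin, Unit.GY), n_fractions)

    rs = pydicom.dcmread(groups["RTSTRUCT"][0])
    rois = {int(r.ROINumber): str(r.ROIName) for r in rs.StructureSetROISequence}
    if roi_name is None and len(rois) == 1:
        roi_name = next(iter(rois.values()))
    matching = [num for num, name in rois.items() if name == roi_name]
    if not matching:
        raise KeyError(f"ROI {roi_name!r} not found; available: {sorted(rois.values())}")
    slices = []
    for rc in rs.ROIContourSequence:
        if int(rc.ReferencedROINumber) != matching[0]:
            continue
        for c in rc.ContourSequence:
            pts = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            slices.append((float(pts[0, 2]), pts[:, :2]))
    gtv = ContourSet(roi_name, slices)

    outcome_path = directory / "outcome.json"
    outcome = json.loads(outcome_path.read_text()) if outcome_path.exists() \
        else {"event": False, "time_months": 60.0}
    return PatientRecord(str(ct_first.PatientID), ct, pet, radiopharm, dose,
                         gtv, outcome["event"], outcome["time_months"])
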