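"""Raster and table IO: NPZ, 8/16-bit PNG, single-frame DICOM, cohort CSV.

NPZ is the lossless interchange format (arrays named ``pixels`` and ``mask``);
PNG round-trips integer-valued phantoms exactly; DICOM reading honours
RescaleSlope/RescaleIntercept so pixels come back on the rescaled intensity
scale, as a CT viewer would show them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from gastroseg.phantoms import CTSlice, MaskPair, PatientRecord, Phase

__all__ = [
    "FormatError",
    "read_slice",
    "write_slice",
    "write_mask",
    "read_mask",
    "read_cohort_csv",
    "write_cohort_csv",
]


class FormatError(ValueError):
    """A file does not parse under the named standard."""


_COHORT_COLUMNS = [
    "patient_id",
    "age_group",
    "sex",
    "diameter_group",
    "tnm_group",
    "chemo",
    "location",
    "recurrence",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    mapping = {".npz": "npz", ".png": "png", ".dcm": "dicom", ".dicom": "dicom"}
    if suffix not in mapping:
        raise FormatError(f"cannot infer format from suffix {suffix!r} of {path}")
    return mapping[suffix]


def write_slice(slc: CTSlice, path: str | Path, fmt: str | None = None) -> Path:
    """Write a slice as NPZ (lossless), 16-bit PNG, or single-frame DICOM."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npz":
        np.savez(
            path,
            pixels=slc.pixels,
            phase=np.array(slc.phase.value),
            pixel_spacing=np.array(slc.pixel_spacing),
            patient_id=np.array(slc.patient_id),
        )
    elif fmt == "png":
        px = slc.pixels
        if not np.allclose(px, np.round(px)) or px.min() < 0 or px.max() > 65535:
            raise FormatError(
                "PNG requires integer pixel values in [0, 65535]; use NPZ for floats"
            )
        Image.fromarray(px.astype(np.uint16)).save(path)
    elif fmt == "dicom":
        _write_dicom(slc, path)
    else:
        raise FormatError(f"unknown slice format {fmt!r}")
    return path


def read_slice(path: str | Path, fmt: str | None = None) -> CTSlice:
    """Read a slice written by :func:`write_slice` (or any compatible file)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "pixels" not in z:
                raise FormatError(f"NPZ file {path} lacks required array 'pixels'")
            return CTSlice(
                pixels=z["pixels"],
                phase=str(z["phase"]) if "phase" in z else Phase.ARTERIAL,
                pixel_spacing=float(z["pixel_spacing"]) if "pixel_spacing" in z else 0.7,
                patient_id=str(z["patient_id"]) if "patient_id" in z else "anon",
            )
    if fmt == "png":
        img = Image.open(path)
        if img.mode not in ("L", "I", "I;16"):
            raise FormatError(f"PNG {path} is not 8/16-bit grayscale (mode={img.mode})")
        return CTSlice(pixels=np.asarray(img, dtype=float))
    if fmt == "dicom":
        return _read_dicom(path)
    raise FormatError(f"unknown slice format {fmt!r}")


def _write_dicom(slc: CTSlice, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    px = slc.pixels
    if not np.allclose(px, np.round(px)):
        raise FormatError("DICOM writer requires integer-valued pixels; use NPZ for floats")
    arr = np.round(px).astype(np.int16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "CT"
    ds.PatientID = slc.patient_id
    ds.SeriesDescription = slc.phase.value
    ds.Rows, ds.Columns = arr.shape
    ds.PixelSpacing = [slc.pixel_spacing, slc.pixel_spacing]
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = 1
    ds.RescaleIntercept = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


def _read_dicom(path: Path) -> CTSlice:
    import pydicom

    try:
        ds = pydicom.dcmread(path)
        arr = ds.pixel_array.astype(float)
    except Exception as exc:  # noqa: BLE001 - rewrap as format error
        raise FormatError(f"cannot read DICOM {path}: {exc}") from exc
    if arr.ndim != 2:
        raise FormatError(f"DICOM {path} is not single-frame (shape {arr.shape})")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", [0.7, 0.7])
    phase = Phase.PORTAL if str(getattr(ds, "SeriesDescription", "")) == "portal" else Phase.ARTERIAL
    return CTSlice(
        pixels=arr,
        phase=phase,
        pixel_spacing=float(spacing[0]),
        patient_id=str(getattr(ds, "PatientID", "anon")),
    )


def write_mask(mask: np.ndarray | MaskPair, path: str | Path, fmt: str | None = None) -> Path:
    """Write a binary mask as NPZ (array 'mask') or 8-bit PNG (0/255)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    arr = mask.ground_truth if isinstance(mask, MaskPair) else np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise FormatError("mask must be binary 0/1")
    arr = arr.astype(np.uint8)
    if fmt == "npz":
        np.savez(path, mask=arr)
    elif fmt == "png":
        Image.fromarray(arr * 255).save(path)
    else:
        raise FormatError(f"unsupported mask format {fmt!r}")
    return path


def read_mask(path: str | Path, fmt: str | None = None) -> np.ndarray:
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "npz":
        with np.load(path, allow_pickle=False) as z:
            if "mask" not in z:
                raise FormatError(f"NPZ file {path} lacks required array 'mask'")
            return z["mask"].astype(np.uint8)
    if fmt == "png":
        arr = np.asarray(Image.open(path))
        return (arr > 0).astype(np.uint8)
    raise FormatError(f"unsupported mask format {fmt!r}")


def write_cohort_csv(records: list[PatientRecord], path: str | Path) -> Path:
    """Write PatientRecords as UTF-8 comma-separated values with a header row."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=_COHORT_COLUMNS)
    df.to_csv(path, index=False)
    return Path(path)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV back into validated PatientRecords."""
    df = pd.read_csv(path)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"cohort CSV {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                PatientRecord(
                    patient_id=str(row["patient_id"]),
                    age_group=row["age_group"],
                    sex=row["sex"],
                    diameter_group=row["diameter_group"],
                    tnm_group=row["tnm_group"],
                    chemo=bool(row["chemo"]),
                    location=row["location"],
                    recurrence=bool(row["recurrence"]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"invalid record {row['patient_id']!r}: {exc}") from exc
    return records
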