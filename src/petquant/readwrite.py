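"""NIfTI/DICOM readers and CSV/JSON report writers.

NIfTI is the canonical volume format (spacing and origin live in the
header); DICOM PET series are read-only, with subject metadata pulled from
the standard radiopharmaceutical headers when present.  Internally arrays
are (z, y, x); on disk NIfTI stores (x, y, z), so data are transposed at the
boundary.  Report CSVs round floats to 4 decimals for readability; the JSON
twins keep full precision.  All writers are deterministic for fixed input.
"""

from __future__ import annotations

import json
from datetime import datetime, timedelta
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

from .calibration import ThresholdRow, ThresholdTable
from .delineation import LesionMetrics
from .errors import FormatError
from .image import VolumetricImage
from .stats import ComparisonReport, metrics_to_frame
from .suv import F18_HALF_LIFE_MIN, SubjectInfo, SuvTriple

__all__ = [
    "read_volume", "write_volume", "read_dicom_series",
    "write_report", "write_threshold_table", "read_threshold_table",
    "write_metrics", "read_metrics_frame",
]

_CSV_DECIMALS = 4


def write_volume(image: VolumetricImage, path: str | Path) -> Path:
    """Write a volume as NIfTI; spacing/origin go into the affine."""
    path = Path(path)
    sz, sy, sx = image.spacing_mm
    oz, oy, ox = image.origin_mm
    affine = np.diag([sx, sy, sz, 1.0])
    affine[:3, 3] = [ox, oy, oz]
    nib.save(nib.Nifti1Image(np.ascontiguousarray(image.data.T), affine), str(path))
    return path


def _read_nifti(path: Path) -> VolumetricImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.ndim}D")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    return VolumetricImage(data.T, spacing_mm=tuple(float(z) for z in zooms[::-1]),
                           origin_mm=tuple(float(o) for o in origin[::-1]))


def read_volume(path: str | Path) -> VolumetricImage:
    """Read a NIfTI file or a DICOM series directory into a volume (Bq/mL)."""
    path = Path(path)
    if path.is_dir():
        image, _ = read_dicom_series(path)
        return image
    return _read_nifti(path)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _parse_dicom_time(date: str, time: str) -> datetime:
    frac = 0.0
    if "." in time:
        time, frac_s = time.split(".")
        frac = float("0." + frac_s)
    return datetime.strptime(date + time.ljust(6, "0"), "%Y%m%d%H%M%S") + timedelta(seconds=frac)


def _subject_from_dataset(ds: "pydicom.Dataset") -> SubjectInfo | None:
    """Extract SUV-relevant subject metadata; None when headers are absent."""
    try:
        rph = ds.RadiopharmaceuticalInformationSequence[0]
        dose_bq = float(rph.RadionuclideTotalDose)
        half_life_min = float(rph.RadionuclideHalfLife) / 60.0
        start = str(getattr(rph, "RadiopharmaceuticalStartTime", "") or "")
        date = str(getattr(ds, "SeriesDate", getattr(ds, "AcquisitionDate", "")))
        scan_t = str(getattr(ds, "SeriesTime", getattr(ds, "AcquisitionTime", "")))
        sex = {"M": "male", "F": "female"}.get(str(getattr(ds, "PatientSex", "")), None)
        weight = float(getattr(ds, "PatientWeight"))
        height_m = getattr(ds, "PatientSize", None)
    except (AttributeError, IndexError, TypeError, ValueError):
        return None
    if sex is None or not date or not start or not scan_t:
        return None
    return SubjectInfo(
        sex=sex,
        body_weight_kg=weight,
        height_cm=float(height_m) * 100.0 if height_m else 170.0,
        injected_activity_MBq=dose_bq / 1e6,
        injection_time=_parse_dicom_time(date, start),
        scan_time=_parse_dicom_time(date, scan_t),
        radionuclide_half_life_min=half_life_min or F18_HALF_LIFE_MIN,
    )


def read_dicom_series(directory: str | Path) -> tuple[VolumetricImage, SubjectInfo | None]:
    """Read a single-frame DICOM PET series into a volume plus metadata.

    Slices are sorted by their axial position; geometry must be consistent
    across slices and rescale information present, otherwise a
    :class:`FormatError` names the offending attribute.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM files in the directory are skipped
            continue
    if not datasets:
        raise FormatError(f"{directory}: no readable DICOM files")

    def zpos(ds):
        return float(ds.ImagePositionPatient[2])

    try:
        datasets.sort(key=zpos)
    except AttributeError as e:
        raise FormatError("missing ImagePositionPatient in series") from e

    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise FormatError("missing PixelSpacing")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    for ds in datasets[1:]:
        if tuple(float(v) for v in ds.PixelSpacing) != (row_sp, col_sp):
            raise FormatError("inconsistent PixelSpacing across slices")
        if ds.pixel_array.shape != first.pixel_array.shape:
            raise FormatError("inconsistent Rows/Columns across slices")
    if len(datasets) > 1:
        gaps = np.diff([zpos(ds) for ds in datasets])
        if np.ptp(gaps) > 1e-3 or gaps[0] <= 0:
            raise FormatError("non-uniform slice spacing (ImagePositionPatient)")
        slice_sp = float(gaps[0])
    else:
        slice_sp = float(getattr(first, "SliceThickness", 0) or 0)
        if slice_sp <= 0:
            raise FormatError("missing SliceThickness for single-slice series")

    slices = []
    for ds in datasets:
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            raise FormatError("missing RescaleSlope/RescaleIntercept")
        slices.append(ds.pixel_array.astype(np.float64) * float(slope) + float(intercept))
    data = np.stack(slices, axis=0)  # (z, y, x)
    ipp = first.ImagePositionPatient
    origin = (float(ipp[2]), float(ipp[1]), float(ipp[0]))
    image = VolumetricImage(data, spacing_mm=(slice_sp, row_sp, col_sp), origin_mm=origin)
    return image, _subject_from_dataset(first)


# ---------------------------------------------------------------------------
# Tables and reports
# ---------------------------------------------------------------------------

def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=f"%.{_CSV_DECIMALS}f", lineterminator="\n")


def write_threshold_table(table: ThresholdTable, base_path: str | Path) -> list[Path]:
    """Write a threshold table as `<base>.csv` (readable) + `<base>.json`
    (full precision, machine-readable round-trip)."""
    base = Path(base_path)
    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")
    _write_csv(table.to_dataframe(), csv_path)
    payload = [
        {"volume_cm3": r.volume_cm3,
         "per_variant": {k: list(v) for k, v in r.per_variant.items()},
         "mean_percent": r.mean_percent,
         "consensus_percent": r.consensus_percent}
        for r in table.rows
    ]
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return [csv_path, json_path]


def read_threshold_table(json_path: str | Path) -> ThresholdTable:
    rows = [
        ThresholdRow(volume_cm3=float(r["volume_cm3"]),
                     per_variant={k: tuple(int(t) for t in v)
                                  for k, v in r["per_variant"].items()},
                     mean_percent=float(r["mean_percent"]),
                     consensus_percent=int(r["consensus_percent"]))
        for r in json.loads(Path(json_path).read_text())
    ]
    return ThresholdTable(rows)


def write_metrics(metrics: list[LesionMetrics], base_path: str | Path) -> list[Path]:
    base = Path(base_path)
    frame = metrics_to_frame(metrics)
    csv_path, json_path = base.with_suffix(".csv"), base.with_suffix(".json")
    _write_csv(frame, csv_path)
    json_path.write_text(frame.to_json(orient="records", indent=2) + "\n")
    return [csv_path, json_path]


def read_metrics_frame(csv_path: str | Path) -> pd.DataFrame:
    return pd.read_csv(csv_path)


def write_report(report: ComparisonReport | ThresholdTable | list, path: str | Path) -> list[Path]:
    """Dispatch writer: comparison report, threshold table, or metrics list.

    ``path`` is a base name; one CSV per table plus a JSON twin is produced.
    """
    if isinstance(report, ThresholdTable):
        return write_threshold_table(report, path)
    if isinstance(report, list):
        return write_metrics(report, path)
    base = Path(path)
    written = []
    payload = {}
    for name, frame in report.to_frames().items():
        p = base.parent / f"{base.stem}_{name}.csv"
        _write_csv(frame, p)
        written.append(p)
        payload[name] = frame.to_dict(orient="records")
    json_path = base.with_suffix(".json")
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
    written.append(json_path)
    return written
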