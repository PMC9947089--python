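"""Readers and writers for dynamic series, ROIs and dose maps.

Dynamic series travel either as paired DICOM series (separate magnitude and
phase series; phase stored as integers mapped to [-pi, pi) through the
standard rescale slope/intercept) or as a compact ``.npz`` array container
with a JSON metadata sidecar.  ROIs are JSON polygon lists; temperature and
dose maps export as float TIFF stacks and plain-text matrices.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pydicom
import tifffile
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .acquisition import AcquisitionParams
from .errors import DataError, UsageError
from .preprocess import RoiSpec
from .thermometry import DynamicSeries

PHASE_LEVELS = 4096  # stored phase integers 0..4095 span [-pi, pi)


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def _base_dataset(acq: AcquisitionParams, study_uid: str, series_uid: str,
                  series_number: int, description: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = MRImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.StudyInstanceUID = study_uid
    ds.SeriesInstanceUID = series_uid
    ds.SeriesNumber = series_number
    ds.SeriesDescription = description
    ds.Modality = "MR"
    ds.PatientName = "synthetic^phantom"
    ds.PatientID = "SYNTH"
    ds.EchoTime = acq.te_s * 1000.0
    ds.RepetitionTime = acq.tr_s * 1000.0
    ds.FlipAngle = acq.flip_deg
    ds.SliceThickness = acq.slice_mm
    ds.MagneticFieldStrength = acq.b0_tesla
    ds.PixelSpacing = [acq.pixel_mm[0], acq.pixel_mm[1]]
    ds.Rows, ds.Columns = acq.matrix
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    return ds


def write_dicom_series(series: DynamicSeries, out_dir: str | Path) -> list[Path]:
    """Write a dynamic series as paired magnitude/phase DICOM series.

    Magnitude frames are linearly rescaled to uint16; phase frames are
    quantized to ``PHASE_LEVELS`` integers with RescaleSlope/Intercept
    mapping stored values to [-pi, pi).  Frame timing is carried in
    TriggerTime (ms); the baseline frame count in ImageComments.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    study_uid = generate_uid()
    paths: list[Path] = []
    mag_max = float(series.magnitude_frames.max())
    mag_slope = mag_max / 65535.0 if mag_max > 0 else 1.0
    phase_slope = 2.0 * np.pi / PHASE_LEVELS
    comment = json.dumps(
        {"baseline_frame_count": series.baseline_frame_count}
    )
    for kind, series_number in (("magnitude", 1), ("phase", 2)):
        series_uid = generate_uid()
        for k in range(series.n_frames):
            ds = _base_dataset(series.acq, study_uid, series_uid,
                               series_number, kind)
            ds.SOPInstanceUID = generate_uid()
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
            ds.InstanceNumber = k + 1
            ds.TriggerTime = float(series.times_s[k]) * 1000.0
            ds.NumberOfTemporalPositions = series.n_frames
            ds.TemporalPositionIdentifier = k + 1
            ds.ImageComments = comment
            if kind == "magnitude":
                ds.ImageType = ["ORIGINAL", "PRIMARY", "M", "ND"]
                stored = np.clip(
                    np.round(series.magnitude_frames[k] / mag_slope), 0, 65535
                ).astype(np.uint16)
                ds.RescaleSlope = mag_slope
                ds.RescaleIntercept = 0.0
            else:
                ds.ImageType = ["ORIGINAL", "PRIMARY", "P", "ND"]
                stored = np.clip(
                    np.round((series.phase_frames[k] + np.pi) / phase_slope),
                    0,
                    PHASE_LEVELS - 1,
                ).astype(np.uint16)
                ds.RescaleSlope = phase_slope
                ds.RescaleIntercept = -np.pi
            ds.PixelData = stored.tobytes()
            path = out_dir / f"{kind}_{k:04d}.dcm"
            ds.save_as(path, enforce_file_format=True)
            paths.append(path)
    return paths


def _frame_sort_key(ds: Dataset):
    t = getattr(ds, "TriggerTime", None)
    if t is not None:
        return (0, float(t))
    return (1, int(getattr(ds, "InstanceNumber", 0)))


def read_dicom_series(
    directory: str | Path, baseline_frame_count: int | None = None
) -> DynamicSeries:
    """Read paired magnitude/phase DICOM series from a directory.

    Frames are classified magnitude vs phase by ImageType (falling back to
    SeriesDescription), ordered by TriggerTime with InstanceNumber fallback,
    and rescaled to physical units via RescaleSlope/Intercept.  The
    baseline frame count is taken from the writer's ImageComments record
    unless overridden.
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.dcm"))
    if not files:
        raise DataError(f"no DICOM files found in {directory}")
    mag_ds: list[Dataset] = []
    phs_ds: list[Dataset] = []
    for f in files:
        ds = pydicom.dcmread(f)
        itype = [str(x).upper() for x in getattr(ds, "ImageType", [])]
        desc = str(getattr(ds, "SeriesDescription", "")).lower()
        if "P" in itype or "phase" in desc:
            phs_ds.append(ds)
        elif "M" in itype or "magnitude" in desc:
            mag_ds.append(ds)
        else:
            raise DataError(f"cannot classify {f.name} as magnitude or phase")
    if len(mag_ds) != len(phs_ds):
        raise DataError(
            f"magnitude/phase frame counts differ "
            f"({len(mag_ds)} vs {len(phs_ds)})"
        )
    mag_ds.sort(key=_frame_sort_key)
    phs_ds.sort(key=_frame_sort_key)

    def _pixels(ds: Dataset) -> np.ndarray:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        return arr * slope + intercept

    mag = np.stack([_pixels(d) for d in mag_ds])
    phs = np.stack([_pixels(d) for d in phs_ds])

    ref = mag_ds[0]
    times = np.array(
        [float(getattr(d, "TriggerTime", 1000.0 * i)) / 1000.0
         for i, d in enumerate(mag_ds)]
    )
    interval = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    spacing = [float(x) for x in ref.PixelSpacing]
    acq = AcquisitionParams(
        te_s=float(ref.EchoTime) / 1000.0,
        tr_s=float(getattr(ref, "RepetitionTime", 31.0)) / 1000.0,
        flip_deg=float(getattr(ref, "FlipAngle", 13.0)),
        slice_mm=float(getattr(ref, "SliceThickness", 4.0)),
        fov_mm=(spacing[0] * int(ref.Rows), spacing[1] * int(ref.Columns)),
        matrix=(int(ref.Rows), int(ref.Columns)),
        frame_interval_s=interval,
        b0_tesla=float(getattr(ref, "MagneticFieldStrength", 1.5)),
    )
    if baseline_frame_count is None:
        baseline_frame_count = 5
        comment = getattr(ref, "ImageComments", "")
        try:
            baseline_frame_count = int(
                json.loads(comment)["baseline_frame_count"]
            )
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
    return DynamicSeries(
        magnitude_frames=mag,
        phase_frames=phs,
        times_s=times,
        acq=acq,
        baseline_frame_count=baseline_frame_count,
    )


# ---------------------------------------------------------------------------
# Portable array container (.npz + JSON sidecar)
# ---------------------------------------------------------------------------

def write_npz_series(series: DynamicSeries, path: str | Path) -> Path:
    """Write a dynamic series as ``.npz`` with a ``.json`` metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        magnitude=series.magnitude_frames,
        phase=series.phase_frames,
        times_s=series.times_s,
    )
    sidecar = {
        "acq": asdict(series.acq),
        "baseline_frame_count": series.baseline_frame_count,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def read_npz_series(path: str | Path) -> DynamicSeries:
    path = Path(path)
    data = np.load(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    acq_dict = dict(sidecar["acq"])
    acq_dict["fov_mm"] = tuple(acq_dict["fov_mm"])
    acq_dict["matrix"] = tuple(acq_dict["matrix"])
    return DynamicSeries(
        magnitude_frames=data["magnitude"],
        phase_frames=data["phase"],
        times_s=data["times_s"],
        acq=AcquisitionParams(**acq_dict),
        baseline_frame_count=int(sidecar["baseline_frame_count"]),
    )


# ---------------------------------------------------------------------------
# ROIs, maps
# ---------------------------------------------------------------------------

def write_roi_json(roi: RoiSpec, path: str | Path) -> Path:
    path = Path(path)
    if roi.vertices is not None:
        payload = {"type": "polygon", "vertices": roi.vertices.tolist()}
    else:
        payload = {"type": "raster", "raster": roi.raster.astype(int).tolist()}
    path.write_text(json.dumps(payload))
    return path


def read_roi_json(path: str | Path) -> RoiSpec:
    payload = json.loads(Path(path).read_text())
    if payload.get("type") == "polygon":
        return RoiSpec.from_polygon(payload["vertices"])
    if payload.get("type") == "raster":
        return RoiSpec.from_raster(np.asarray(payload["raster"], dtype=bool))
    raise UsageError(f"unrecognized ROI file {path}")


def write_map_tiff(array: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D map or stack as float32 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


def write_map_text(array: np.ndarray, path: str | Path) -> Path:
    """Write a 2-D map as a plain-text matrix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.asarray(array, dtype=float), fmt="%.6g")
    return path
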