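"""Readers and writers for series, geometry, curves, grids and manifests.

Conventions: pixel coordinates are 0-based ``[x, y]`` (column, row); all
times are seconds; MBF is mL/min/g; angles in user-facing files are
degrees.  Dynamic series are stored as one 3D NIfTI per slice with axes
``[time, row, col]`` and an optional JSON sidecar (``<stem>.times.json``)
holding the frame times and slice label; DICOM series directories are
read-only, frames ordered by trigger time (falling back to instance
number).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
import yaml

from .bullseye import BullseyeGrid, N_ANGLES, N_LAYERS
from .geometry import SliceGeometry
from .kinetics import ArterialInput, ConcentrationCurve, DynamicSeries

__all__ = [
    "read_series",
    "write_series_nifti",
    "read_geometry",
    "write_geometry",
    "read_aif_csv",
    "write_aif_csv",
    "read_mask",
    "write_mask",
    "write_map",
    "read_map",
    "bullseye_to_csv",
    "bullseye_from_csv",
    "bullseye_to_json",
    "read_manifest",
    "default_config",
    "load_config",
    "write_config",
]


# ---------------------------------------------------------------------------
# dynamic series

def _sidecar(path: Path) -> Path:
    p = Path(path)
    stem = p.name
    for suffix in (".nii.gz", ".nii"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    return p.with_name(stem + ".times.json")


def write_series_nifti(series: DynamicSeries, path) -> None:
    """Write a dynamic series as a 3D ``[time, row, col]`` NIfTI + sidecar."""
    img = nib.Nifti1Image(np.asarray(series.frames, dtype=np.float64), np.eye(4))
    nib.save(img, str(path))
    sidecar = {
        "frame_times_s": [float(t) for t in series.frame_times],
        "slice_label": series.slice_label,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def read_series(path, frame_interval: float | None = None,
                slice_label: str | None = None) -> DynamicSeries:
    """Read a dynamic series from a NIfTI file or a DICOM directory.

    Frame times come from the JSON sidecar (NIfTI) or trigger times
    (DICOM); when absent, ``frame_interval`` seconds per frame is used.
    """
    path = Path(path)
    if path.is_dir():
        return _read_dicom_dir(path, frame_interval, slice_label)
    img = nib.load(str(path))
    frames = np.asarray(img.get_fdata(), dtype=float)
    if frames.ndim != 3:
        raise ValueError(f"expected a 3D [time, row, col] NIfTI, got {frames.ndim}D")
    sidecar = _sidecar(path)
    times = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        times = np.asarray(meta.get("frame_times_s"), dtype=float)
        slice_label = slice_label or meta.get("slice_label")
    if times is None:
        if frame_interval is None:
            raise ValueError("no sidecar frame times; provide frame_interval")
        times = frame_interval * np.arange(frames.shape[0])
    if not np.all(np.diff(times) > 0):
        raise ValueError("frame times are not strictly increasing")
    return DynamicSeries(frames=frames, frame_times=times,
                         slice_label=slice_label or "mid")


def _read_dicom_dir(path: Path, frame_interval, slice_label) -> DynamicSeries:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise ValueError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def order_key(ds):
        trig = getattr(ds, "TriggerTime", None)
        if trig is not None:
            return (0, float(trig))
        return (1, int(getattr(ds, "InstanceNumber", 0)))

    datasets.sort(key=order_key)
    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    trig = [getattr(ds, "TriggerTime", None) for ds in datasets]
    if all(t is not None for t in trig):
        times = np.asarray([float(t) for t in trig]) / 1000.0  # ms -> s
    elif frame_interval is not None:
        times = frame_interval * np.arange(len(datasets))
    else:
        raise ValueError("DICOM series lacks trigger times; provide frame_interval")
    if not np.all(np.diff(times) > 0):
        raise ValueError("DICOM frame times are not strictly increasing")
    return DynamicSeries(frames=frames, frame_times=times,
                         slice_label=slice_label or "mid")


# ---------------------------------------------------------------------------
# geometry JSON

def write_geometry(geometry: SliceGeometry, path) -> None:
    doc = {
        "schema": "qperf-geometry-v1",
        "coordinates": "0-based [x, y] pixel coordinates (x = column, y = row)",
        "slice_label": geometry.slice_label,
        "endo": geometry.endo_contour.tolist(),
        "epi": geometry.epi_contour.tolist(),
        "rv_anterior": geometry.rv_anterior.tolist(),
        "rv_inferior": geometry.rv_inferior.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_geometry(path) -> SliceGeometry:
    doc = json.loads(Path(path).read_text())
    return SliceGeometry(
        endo_contour=np.asarray(doc["endo"], dtype=float),
        epi_contour=np.asarray(doc["epi"], dtype=float),
        rv_anterior=np.asarray(doc["rv_anterior"], dtype=float),
        rv_inferior=np.asarray(doc["rv_inferior"], dtype=float),
        slice_label=doc["slice_label"],
    )


# ---------------------------------------------------------------------------
# AIF CSV

def write_aif_csv(aif: ArterialInput, path) -> None:
    pd.DataFrame({"time_s": aif.times, "value": aif.values}).to_csv(path, index=False)


def read_aif_csv(path) -> ArterialInput:
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError("AIF CSV needs columns time_s,value")
    return ArterialInput(
        ConcentrationCurve(values=df["value"].to_numpy(float),
                           times=df["time_s"].to_numpy(float))
    )


# ---------------------------------------------------------------------------
# masks and maps (NIfTI, 2D)

def write_mask(mask: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), np.eye(4))
    nib.save(img, str(path))


def read_mask(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).get_fdata())
    if arr.ndim != 2:
        raise ValueError("expected a 2D mask")
    return arr > 0.5


def write_map(mbf: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(mbf, dtype=np.float64), np.eye(4)), str(path))


def read_map(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)


# ---------------------------------------------------------------------------
# bullseye grids

def bullseye_to_csv(grid: BullseyeGrid, path) -> None:
    """Long-format CSV with columns slice, layer, angle, mbf.

    ``layer`` counts 0 (subendocardium) to 9 (subepicardium); ``angle`` is
    the bin centre in degrees from the anterior RV insertion point.
    """
    s, l, a = np.meshgrid(
        np.arange(3), np.arange(N_LAYERS), np.arange(N_ANGLES), indexing="ij"
    )
    labels = np.array(["basal", "mid", "apical"])
    df = pd.DataFrame(
        {
            "slice": labels[s.ravel()],
            "layer": l.ravel(),
            "angle": (a.ravel() + 0.5) * (360.0 / N_ANGLES),
            "mbf": grid.values.ravel(),
        }
    )
    df.to_csv(path, index=False)


def bullseye_from_csv(path) -> BullseyeGrid:
    df = pd.read_csv(path)
    values = np.full((3, N_LAYERS, N_ANGLES), np.nan)
    slice_idx = {"basal": 0, "mid": 1, "apical": 2}
    s = df["slice"].map(slice_idx).to_numpy()
    l = df["layer"].to_numpy(int)
    a = np.round(df["angle"].to_numpy(float) / (360.0 / N_ANGLES) - 0.5).astype(int)
    values[s, l, a] = df["mbf"].to_numpy(float)
    return BullseyeGrid(values)


def bullseye_to_json(grid: BullseyeGrid, path) -> None:
    doc = {
        "schema": "qperf-bullseye-v1",
        "axes": ["slice (basal, mid, apical)", "layer (subendo->subepi)",
                 "angle bin (6 deg, from anterior RV insertion)"],
        "values": [
            [[None if not np.isfinite(x) else float(x) for x in row] for row in sl]
            for sl in grid.values
        ],
    }
    Path(path).write_text(json.dumps(doc))


# ---------------------------------------------------------------------------
# cohort manifest and configuration

MANIFEST_COLUMNS = ("patient_id", "slice_label", "series_path", "geometry_path")


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest CSV; paths are resolved relative to the CSV location.

    Required columns: patient_id, slice_label, series_path, geometry_path,
    aif_path.  Optional: reference_mask_path.  Three slice rows per patient.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS + ("aif_path",)) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "reference_mask_path" not in df.columns:
        df["reference_mask_path"] = None
    base = path.parent
    for col in ("series_path", "geometry_path", "aif_path", "reference_mask_path"):
        df[col] = df[col].map(
            lambda p: None if p is None or (isinstance(p, float) and np.isnan(p))
            else str((base / p) if not Path(p).is_absolute() else Path(p))
        )
    counts = df.groupby("patient_id")["slice_label"].nunique()
    if not (counts == 3).all():
        raise ValueError("each patient needs exactly one row per slice level")
    return df


def default_config() -> dict:
    return {
        "baseline_frame_count": 3,
        "frame_interval_s": None,
        "n_layers": N_LAYERS,
        "n_angles": N_ANGLES,
        "median_filter_size": 5,
        "noise_floor_factor": 5.0,
        "seed": 0,
    }


def load_config(path=None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def write_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))
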