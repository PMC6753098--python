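"""File formats: NIfTI volumes, JSON sidecars, CSV logs and fiducials."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cooling import CoolingProfile, SensationLog
from .fatwater import EchoSchedule, EchoSeries, FSFVolume
from .registration import DeformationField, FiducialSet

__all__ = [
    "save_volume",
    "load_volume",
    "write_echo_series",
    "read_echo_series",
    "write_fsf",
    "read_fsf",
    "write_field",
    "read_field",
    "write_cooling_log",
    "read_cooling_log",
    "write_sensation_log",
    "read_sensation_log",
    "write_fiducials",
    "read_fiducials",
    "sha256_file",
]


def _affine(voxel_size_mm=(1.25, 1.25, 4.0)) -> np.ndarray:
    return np.diag(list(voxel_size_mm) + [1.0])


def save_volume(vol: np.ndarray, path, voxel_size_mm=(1.25, 1.25, 4.0)) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(vol), _affine(voxel_size_mm)), str(path))
    return path


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def write_echo_series(series: EchoSeries, prefix, voxel_size_mm=(1.25, 1.25, 4.0)) -> dict:
    """Write one acquisition as magnitude + phase 4-D NIfTI plus a sidecar.

    ``<prefix>_mag.nii.gz``, ``<prefix>_phase.nii.gz`` and ``<prefix>.json``
    (echo times in ms, train structure, acquisition index and timestamp).
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mag_p = prefix.with_name(prefix.name + "_mag.nii.gz")
    ph_p = prefix.with_name(prefix.name + "_phase.nii.gz")
    save_volume(np.abs(series.data), mag_p, voxel_size_mm)
    save_volume(np.angle(series.data), ph_p, voxel_size_mm)
    sidecar = {
        "te_ms": list(series.schedule.te_ms),
        "n_trains": series.schedule.n_trains,
        "train_index": list(series.schedule.train_index),
        "acquisition_index": series.acquisition_index,
        "timestamp_s": series.timestamp_s,
    }
    js_p = prefix.with_name(prefix.name + ".json")
    js_p.write_text(json.dumps(sidecar, indent=1))
    return {"magnitude": mag_p, "phase": ph_p, "sidecar": js_p}


def read_echo_series(prefix) -> EchoSeries:
    prefix = Path(prefix)
    mag = load_volume(prefix.with_name(prefix.name + "_mag.nii.gz"))
    ph = load_volume(prefix.with_name(prefix.name + "_phase.nii.gz"))
    meta = json.loads(prefix.with_name(prefix.name + ".json").read_text())
    sched = EchoSchedule(
        tuple(meta["te_ms"]), meta["n_trains"], tuple(meta["train_index"])
    )
    return EchoSeries(
        mag * np.exp(1j * ph),
        sched,
        acquisition_index=meta.get("acquisition_index", 0),
        timestamp_s=meta.get("timestamp_s", 0.0),
    )


def write_fsf(fsf: FSFVolume, path, voxel_size_mm=(1.25, 1.25, 4.0)) -> Path:
    """FSF map as NIfTI; invalid voxels are stored as NaN."""
    vals = np.where(fsf.valid, fsf.fsf, np.nan)
    return save_volume(vals, path, voxel_size_mm)


def read_fsf(path) -> FSFVolume:
    vals = load_volume(path)
    valid = np.isfinite(vals)
    return FSFVolume(vals, valid)


def write_field(field: DeformationField, path, voxel_size_mm=(1.25, 1.25, 4.0)) -> Path:
    return save_volume(field.disp, path, voxel_size_mm)


def read_field(path) -> DeformationField:
    return DeformationField(load_volume(path))


def write_cooling_log(profile: CoolingProfile, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": profile.time_min * 60.0,
            "set_temp_C": profile.set_temp_c,
            "actual_temp_C": profile.actual_temp_c,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# thermoneutral_C={profile.thermoneutral_c}\n")
        df.to_csv(fh, index=False)
    return path


def read_cooling_log(path) -> CoolingProfile:
    path = Path(path)
    first = path.read_text().splitlines()[0]
    tn = 32.0
    if first.startswith("#") and "thermoneutral_C=" in first:
        tn = float(first.split("=", 1)[1])
    df = pd.read_csv(path, comment="#")
    return CoolingProfile(
        df["time_s"].to_numpy() / 60.0,
        df["set_temp_C"].to_numpy(),
        df["actual_temp_C"].to_numpy(),
        thermoneutral_c=tn,
    )


def write_sensation_log(log: SensationLog, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": log.time_min * 60.0, "sensation": log.sensation}).to_csv(
        path, index=False
    )
    return path


def read_sensation_log(path) -> SensationLog:
    df = pd.read_csv(path)
    return SensationLog(df["time_s"].to_numpy() / 60.0, df["sensation"].to_numpy())


def write_fiducials(fids: FiducialSet, path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "label": list(fids.labels),
            "slice": fids.points[:, 0],
            "row": fids.points[:, 1],
            "col": fids.points[:, 2],
        }
    ).to_csv(path, index=False)
    return path


def read_fiducials(path) -> FiducialSet:
    df = pd.read_csv(path)
    pts = df[["slice", "row", "col"]].to_numpy(dtype=float)
    return FiducialSet(pts, tuple(df["label"].astype(str)))


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
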