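"""FSF decade assignment, longitudinal tracking and bootstrap ROI sizing.

Voxels in a tissue ROI are assigned to an FSF decade — {0-10%}, {10-20%},
... {90-100%} — according to their *thermoneutral* (first acquisition) FSF
value, and keep that identity across every later acquisition.  Bins are
half-open [d, d+10) except the top bin, which is closed so that FSF = 100
belongs to the 90-100% decade.  Decades holding fewer than 60 voxels are
excluded from summaries; the 60-voxel floor itself comes from bootstrap
resampling of voxel-wise FSF populations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .fatwater import FSFVolume

__all__ = [
    "DecadeTrack",
    "BootstrapRoiSize",
    "assign_decades",
    "summarize_decades",
    "bootstrap_min_roi_size",
    "decade_of",
]

N_DECADES = 10


def decade_of(fsf: np.ndarray) -> np.ndarray:
    """Decade index 0..9 of an FSF value; 100 maps to the top (closed) bin."""
    fsf = np.asarray(fsf, dtype=float)
    return np.minimum(np.floor(fsf / 10.0), 9).astype(int)


@dataclass
class DecadeTrack:
    """Frozen voxel-to-decade assignment from the thermoneutral acquisition."""

    voxel_index: np.ndarray  # flat indices into the volume
    decade: np.ndarray  # 0..9 per tracked voxel
    grid_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.voxel_index = np.asarray(self.voxel_index)
        self.decade = np.asarray(self.decade)
        if self.voxel_index.shape != self.decade.shape:
            raise ValueError("voxel_index and decade must align")

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.decade, minlength=N_DECADES)

    def included(self, min_voxels: int = 60) -> np.ndarray:
        """Decades with at least ``min_voxels`` tracked voxels."""
        return self.counts >= min_voxels


def assign_decades(fsf_tn: FSFVolume, mask: np.ndarray) -> DecadeTrack:
    """Assign ROI voxels to FSF decades from the thermoneutral map."""
    mask = np.asarray(mask, bool)
    if mask.shape != fsf_tn.fsf.shape:
        raise ValueError("mask and FSF map shapes differ")
    if np.any(mask & ~fsf_tn.valid):
        raise ValueError("mask contains voxels invalid in the thermoneutral map")
    idx = np.flatnonzero(mask.ravel())
    vals = fsf_tn.fsf.ravel()[idx]
    return DecadeTrack(idx, decade_of(vals), fsf_tn.fsf.shape)


def summarize_decades(
    track: DecadeTrack,
    fsf_series: Sequence[FSFVolume],
    dose_series: Sequence[float] | None = None,
    sensation_series: Sequence[float] | None = None,
    min_voxels: int = 60,
    tissue: str = "bat",
) -> pd.DataFrame:
    """Per-acquisition, per-decade mean FSF table (tidy format).

    The voxel membership of each decade never changes across acquisitions;
    decades with fewer than ``min_voxels`` tracked voxels are excluded
    entirely.  Voxels invalid in a given acquisition are dropped from that
    acquisition's mean only.
    """
    T = len(fsf_series)
    dose = np.full(T, np.nan) if dose_series is None else np.asarray(dose_series, float)
    sens = (
        np.full(T, np.nan)
        if sensation_series is None
        else np.asarray(sensation_series, float)
    )
    if dose.size != T or sens.size != T:
        raise ValueError("dose/sensation series must match the FSF series length")
    include = track.included(min_voxels)
    rows = []
    for t, vol in enumerate(fsf_series):
        if vol.fsf.shape != track.grid_shape:
            raise ValueError(
                f"acquisition {t + 1} not registered to the tracking grid "
                f"(shape {vol.fsf.shape} != {track.grid_shape})"
            )
        flat = vol.fsf.ravel()
        flat_valid = vol.valid.ravel()
        for d in range(N_DECADES):
            if not include[d]:
                continue
            vox = track.voxel_index[track.decade == d]
            ok = flat_valid[vox]
            vals = flat[vox][ok]
            rows.append(
                {
                    "acquisition": t + 1,
                    "tissue": tissue,
                    "decade": d * 10,
                    "n_voxels": int(ok.sum()),
                    "mean_fsf": float(vals.mean()) if vals.size else np.nan,
                    "norm_dose": dose[t],
                    "sensation": sens[t],
                }
            )
    return pd.DataFrame(rows)


@dataclass
class BootstrapRoiSize:
    """Result of the bootstrap minimum-ROI-size search."""

    min_n: int
    half_width_limit: float
    n_boot: int
    query_n: int | None = None
    half_width_at_query: float | None = None


def _bootstrap_half_width(
    values: np.ndarray, n: int, n_boot: int, rng: np.random.Generator
) -> float:
    means = values[rng.integers(0, values.size, size=(n_boot, n))].mean(axis=1)
    lo, hi = np.percentile(means, [2.5, 97.5])
    return float((hi - lo) / 2.0)


def bootstrap_min_roi_size(
    values: Sequence[float],
    half_width_limit: float = 5.0,
    n_boot: int = 1000,
    seed: int | None = None,
    query_n: int | None = None,
    n_start: int = 2,
) -> BootstrapRoiSize:
    """Smallest subsample size whose bootstrap 95% half-width meets a limit.

    For increasing ``n``, draws ``n_boot`` subsamples of size ``n`` (with
    replacement) from the voxel-wise FSF population, computes the 95%
    percentile interval of the subsample mean, and returns the first ``n``
    whose half-width is at or below ``half_width_limit`` (pp).  Optionally
    also reports the half-width at a queried ``n``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 100:
        raise ValueError("need at least 100 population values")
    if half_width_limit <= 0:
        raise ValueError("half-width limit must be positive")
    rng = np.random.default_rng(seed)
    hw_query = None
    if query_n is not None:
        hw_query = _bootstrap_half_width(values, int(query_n), n_boot, rng)
    min_n = None
    for n in range(max(n_start, 2), values.size + 1):
        if _bootstrap_half_width(values, n, n_boot, rng) <= half_width_limit:
            min_n = n
            break
    if min_n is None:
        raise ValueError("half-width limit not reachable within the population size")
    return BootstrapRoiSize(
        min_n=min_n,
        half_width_limit=float(half_width_limit),
        n_boot=int(n_boot),
        query_n=None if query_n is None else int(query_n),
        half_width_at_query=hw_query,
    )
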