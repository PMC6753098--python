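"""Tissue ROI construction on the thermoneutral FSF map.

Manual slice-wise delineation is emulated by seed masks (phantom truth
labels or user-supplied masks).  During delineation of the BAT boundary the
displayed FSF range is constrained (default 30-80%) to limit inclusion of
adjacent muscle and subcutaneous fat: here that is emulated by removing
ROI *boundary-layer* voxels whose thermoneutral FSF falls outside the
window — interior membership, once set, is never FSF-thresholded by this
step.  Erosion (one in-plane pass) and explicit FSF thresholds are separate
operations applied afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.ndimage import binary_erosion

from .fatwater import FSFVolume
from .registration import slice_range_mask

__all__ = [
    "TissueROISet",
    "build_roi",
    "erode_once",
    "merge_bilateral",
    "apply_fsf_threshold",
]

# 4-connected in-plane structuring element (slices are thick, so erosion
# acts per slice).
_CROSS_IN_PLANE = np.array(
    [[[0], [1], [0]], [[1], [1], [1]], [[0], [1], [0]]], dtype=bool
)


@dataclass
class TissueROISet:
    """Disjoint tissue masks with their construction provenance."""

    masks: dict[str, np.ndarray]
    display_window: tuple[float, float]
    slice_range: tuple[int, int]
    bilateral_merged: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = None
        for name, m in self.masks.items():
            m = np.asarray(m, bool)
            self.masks[name] = m
            if total is None:
                total = m.astype(int).copy()
            else:
                if m.shape != total.shape:
                    raise ValueError("all masks must share a shape")
                total += m
        if total is not None and total.max() > 1:
            raise ValueError("tissue masks must be disjoint")


def erode_once(mask: np.ndarray) -> np.ndarray:
    """One in-plane erosion (4-connected cross), applied slice by slice.

    Trims one voxel layer from each in-plane boundary to reduce partial
    volume contamination at ROI edges.
    """
    mask = np.asarray(mask, bool)
    if mask.ndim == 2:
        return binary_erosion(mask[:, :, None], structure=_CROSS_IN_PLANE)[:, :, 0]
    if mask.ndim != 3:
        raise ValueError("mask must be 2-D or 3-D")
    return binary_erosion(mask, structure=_CROSS_IN_PLANE)


def merge_bilateral(left_mask: np.ndarray, right_mask: np.ndarray) -> np.ndarray:
    """Union of two disjoint (left/right) masks into one bilateral ROI."""
    left_mask = np.asarray(left_mask, bool)
    right_mask = np.asarray(right_mask, bool)
    if left_mask.shape != right_mask.shape:
        raise ValueError("masks must share a shape")
    if np.any(left_mask & right_mask):
        raise ValueError("left and right masks overlap")
    return left_mask | right_mask


def apply_fsf_threshold(
    fsf_tn: FSFVolume, mask: np.ndarray, lo: float, hi: float
) -> np.ndarray:
    """Retain mask voxels whose *thermoneutral* FSF lies in [lo, hi].

    Membership is decided once, on the baseline map, and stays frozen for
    all later acquisitions (voxel tracking).
    """
    if not (0 <= lo < hi <= 100):
        raise ValueError(f"threshold bounds ({lo}, {hi}) must satisfy 0 <= lo < hi <= 100")
    mask = np.asarray(mask, bool)
    if mask.shape != fsf_tn.fsf.shape:
        raise ValueError("mask and FSF map shapes differ")
    with np.errstate(invalid="ignore"):
        inside = (fsf_tn.fsf >= lo) & (fsf_tn.fsf <= hi)
    return mask & fsf_tn.valid & inside


def _in_plane_boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~erode_once(mask)


def build_roi(
    fsf_tn: FSFVolume,
    seed_masks: Mapping[str, np.ndarray],
    display_window: tuple[float, float] = (30.0, 80.0),
    slice_range: tuple[int, int] = (6, 13),
    window_tissues: tuple[str, ...] = ("bat", "bat_left", "bat_right"),
) -> TissueROISet:
    """Build tissue ROIs on the thermoneutral FSF map.

    Each seed mask is restricted to the analysis slice range and to voxels
    with a usable separation (erroneous voxels removed).  For BAT masks the
    display window constrains boundary candidates only (see module
    docstring); a window of (0, 100) imposes no restriction.
    """
    w0, w1 = display_window
    if not (0 <= w0 < w1 <= 100):
        raise ValueError("display window must satisfy 0 <= lo < hi <= 100")
    if not fsf_tn.valid.any():
        raise ValueError("FSF map contains no valid voxels")
    srange = slice_range_mask(fsf_tn.fsf.shape, *slice_range)
    masks: dict[str, np.ndarray] = {}
    for name, seed in seed_masks.items():
        seed = np.asarray(seed, bool)
        if seed.shape != fsf_tn.fsf.shape:
            raise ValueError(f"seed mask {name!r} shape differs from FSF map")
        if not seed.any():
            raise ValueError(f"seed mask {name!r} is empty")
        m = seed & srange & fsf_tn.valid
        if name in window_tissues and (w0, w1) != (0.0, 100.0):
            boundary = _in_plane_boundary(m)
            with np.errstate(invalid="ignore"):
                outside = (fsf_tn.fsf < w0) | (fsf_tn.fsf > w1)
            m = m & ~(boundary & outside)
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty after masking")
        masks[name] = m
    return TissueROISet(
        masks,
        display_window=(float(w0), float(w1)),
        slice_range=tuple(slice_range),
        provenance={"window_tissues": tuple(window_tissues)},
    )
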