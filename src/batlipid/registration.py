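"""Nonrigid motion recovery, FSF-map warping and fiducial validation.

Inter-acquisition body motion is recovered with a multi-resolution
demons-style registration (SimpleITK) on water magnitude volumes; the
resulting displacement fields are applied to the FSF maps so that a voxel
can be followed across the whole cooling protocol.  Registration quality is
quantified with in-plane Euclidean distances between manually-placed (here:
phantom-defined) fiducial points before and after registration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import map_coordinates

from .fatwater import FSFVolume

__all__ = [
    "DeformationField",
    "FiducialSet",
    "RegistrationOptions",
    "RegistrationReport",
    "register_nonrigid",
    "warp_fsf",
    "warp_scalar",
    "validate_fiducials",
    "constrain_slices",
]


@dataclass
class DeformationField:
    """Per-voxel 3-D displacement in voxel units, shape (nx, ny, nz, 3).

    ``disp[..., a]`` is the displacement along array axis ``a``.  The field
    follows the resampling convention: the registered (or recovered) volume
    is ``moving(x + disp(x))``, i.e. it maps reference-frame coordinates
    into the moving frame.
    """

    disp: np.ndarray

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=float)
        if self.disp.ndim != 4 or self.disp.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacement field must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.disp.shape[:3]

    @classmethod
    def identity(cls, shape: tuple[int, int, int]) -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,)))


@dataclass
class FiducialSet:
    """Labelled control points, each (slice, row, col) in voxel coordinates."""

    points: np.ndarray  # (N, 3) float, (slice, row, col)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3): slice, row, col")
        if len(self.labels) != len(self.points):
            raise ValueError("one label per point required")


@dataclass
class RegistrationReport:
    """In-plane fiducial distances (pixels) before and after registration."""

    labels: tuple[str, ...]
    distance_before: np.ndarray
    distance_after: np.ndarray

    @property
    def median_before(self) -> float:
        return float(np.median(self.distance_before))

    @property
    def median_after(self) -> float:
        return float(np.median(self.distance_after))

    @staticmethod
    def _iqr(x: np.ndarray) -> float:
        q1, q3 = np.percentile(x, [25, 75])
        return float(q3 - q1)

    @property
    def iqr_before(self) -> float:
        return self._iqr(self.distance_before)

    @property
    def iqr_after(self) -> float:
        return self._iqr(self.distance_after)


@dataclass
class RegistrationOptions:
    """Multi-resolution demons settings.

    ``levels`` are per-axis shrink factors from coarse to fine (the slice
    axis is shrunk less because slices are thick); ``iterations`` gives the
    demons iteration count per level and ``field_sigma_vox`` the Gaussian
    smoothing of the displacement field (voxels, at each level's grid).
    """

    levels: tuple[tuple[int, int, int], ...] = ((4, 4, 2), (2, 2, 1))
    iterations: tuple[int, ...] = (80, 40)
    #: fluid-like regularization: Gaussian smoothing of each demons *update*
    #: (suppresses noise/texture chasing without shrinking the accumulated
    #: displacement, which total-field smoothing would)
    update_sigma_vox: float = 2.0
    #: diffusion-like regularization of the accumulated field; mild, since
    #: strong total-field smoothing systematically under-recovers motion
    field_sigma_vox: float = 1.0
    histogram_match: bool = True


def _to_sitk(vol: np.ndarray) -> sitk.Image:
    # sitk indexes (x, y, z) = our (axis0, axis1, axis2); GetImageFromArray
    # expects the reversed (z, y, x) layout.
    return sitk.GetImageFromArray(
        np.ascontiguousarray(vol.transpose(2, 1, 0).astype(np.float64))
    )


def _shrink(img: sitk.Image, factors: tuple[int, int, int]) -> sitk.Image:
    if all(f == 1 for f in factors):
        return img
    var = [max((f / 2.0) ** 2 - 0.25, 0.0) for f in factors]
    sm = sitk.DiscreteGaussian(img, var) if any(v > 0 for v in var) else img
    return sitk.Shrink(sm, list(factors))


def register_nonrigid(
    fixed_water: np.ndarray,
    moving_water: np.ndarray,
    options: RegistrationOptions | None = None,
) -> DeformationField:
    """Recover the displacement field aligning ``moving_water`` to ``fixed_water``.

    Multi-resolution symmetric-forces demons on intensity volumes (water
    magnitude of the first retained echo).  Deterministic for fixed options.
    The returned field warps the moving volume onto the fixed grid via
    ``moving(x + disp(x))``.
    """
    opts = options or RegistrationOptions()
    fixed_water = np.asarray(fixed_water, dtype=float)
    moving_water = np.asarray(moving_water, dtype=float)
    if fixed_water.shape != moving_water.shape:
        raise ValueError("fixed and moving volumes must share a shape")
    if fixed_water.ndim != 3:
        raise ValueError("expected 3-D intensity volumes")
    f_img = _to_sitk(fixed_water)
    m_img = _to_sitk(moving_water)
    if opts.histogram_match:
        m_img = sitk.HistogramMatching(
            m_img, f_img, numberOfHistogramLevels=256, numberOfMatchPoints=12
        )
    disp: sitk.Image | None = None
    for factors, iters in zip(opts.levels, opts.iterations):
        f_l = _shrink(f_img, factors)
        m_l = _shrink(m_img, factors)
        if disp is None:
            disp_l = sitk.Image(f_l.GetSize(), sitk.sitkVectorFloat64, 3)
            disp_l.CopyInformation(f_l)
        else:
            disp_l = sitk.Resample(
                disp, f_l, sitk.Transform(), sitk.sitkLinear, 0.0, disp.GetPixelID()
            )
        demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
        demons.SetNumberOfIterations(int(iters))
        demons.SetSmoothUpdateField(opts.update_sigma_vox > 0)
        demons.SetUpdateFieldStandardDeviations(max(opts.update_sigma_vox, 1e-3))
        demons.SetSmoothDisplacementField(opts.field_sigma_vox > 0)
        demons.SetStandardDeviations(max(opts.field_sigma_vox, 1e-3))
        disp = demons.Execute(f_l, m_l, disp_l)
    if disp.GetSize() != f_img.GetSize():
        disp = sitk.Resample(
            disp, f_img, sitk.Transform(), sitk.sitkLinear, 0.0, disp.GetPixelID()
        )
    arr = sitk.GetArrayFromImage(disp)  # (z, y, x, 3), components (x, y, z)
    return DeformationField(arr.transpose(2, 1, 0, 3))


def _sample_coords(shape: tuple[int, int, int], disp: np.ndarray) -> np.ndarray:
    grid = np.indices(shape, dtype=float)
    return grid + np.moveaxis(disp, -1, 0)


def warp_scalar(
    vol: np.ndarray, field: DeformationField, order: int = 1, cval: float = 0.0
) -> np.ndarray:
    """Resample ``vol`` at reference coordinates displaced by ``field``."""
    coords = _sample_coords(vol.shape, field.disp)
    return map_coordinates(vol, coords, order=order, mode="constant", cval=cval)


def warp_fsf(fsf: FSFVolume, field: DeformationField) -> FSFVolume:
    """Apply a displacement field to an FSF map.

    Valid voxels are interpolated linearly with validity-weight
    normalization; the validity mask itself is warped with nearest-neighbour
    sampling.  Samples falling outside the grid become invalid; interpolated
    values are re-clipped to [0, 100].
    """
    if fsf.fsf.shape != field.grid_shape:
        raise ValueError("FSF map and field shapes differ")
    if not field.disp.any():
        return fsf.copy()
    coords = _sample_coords(fsf.fsf.shape, field.disp)
    filled = np.where(fsf.valid, fsf.fsf, 0.0)
    num = map_coordinates(filled, coords, order=1, mode="constant", cval=0.0)
    den = map_coordinates(
        fsf.valid.astype(float), coords, order=1, mode="constant", cval=0.0
    )
    valid_nn = map_coordinates(
        fsf.valid.astype(np.uint8), coords, order=0, mode="constant", cval=0
    ).astype(bool)
    in_bounds = np.ones(fsf.fsf.shape, dtype=bool)
    for ax, n in enumerate(fsf.fsf.shape):
        in_bounds &= (coords[ax] >= 0) & (coords[ax] <= n - 1)
    valid = valid_nn & in_bounds & (den > 0.5)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = num / np.maximum(den, 1e-12)
    vals = np.clip(vals, 0.0, 100.0)
    return FSFVolume(np.where(valid, vals, np.nan), valid)


def validate_fiducials(
    fixed: FiducialSet, moving_before: FiducialSet, moving_after: FiducialSet
) -> RegistrationReport:
    """In-plane Euclidean distances to the fixed fiducials, before/after."""
    if not (fixed.labels == moving_before.labels == moving_after.labels):
        raise ValueError("fiducial labels must match across point sets")
    d_before = np.linalg.norm(moving_before.points[:, 1:] - fixed.points[:, 1:], axis=1)
    d_after = np.linalg.norm(moving_after.points[:, 1:] - fixed.points[:, 1:], axis=1)
    return RegistrationReport(fixed.labels, d_before, d_after)


def constrain_slices(volume: np.ndarray, first: int = 6, last: int = 13) -> np.ndarray:
    """Restrict a volume to an inclusive, 1-based slice range (axis 2).

    The default (6, 13) keeps 8 of 15 slices, trimming the slice extremes
    where registration artifacts concentrate.
    """
    volume = np.asarray(volume)
    if volume.ndim < 3:
        raise ValueError("expected a volume with a slice axis (axis 2)")
    n = volume.shape[2]
    if first < 1 or last > n or first > last:
        raise ValueError(f"slice range ({first}, {last}) invalid for {n} slices")
    return volume[:, :, first - 1 : last]


def slice_range_mask(shape: tuple[int, int, int], first: int = 6, last: int = 13) -> np.ndarray:
    """Boolean mask selecting the 1-based inclusive slice range."""
    n = shape[2]
    if first < 1 or last > n or first > last:
        raise ValueError(f"slice range ({first}, {last}) invalid for {n} slices")
    m = np.zeros(shape, dtype=bool)
    m[:, :, first - 1 : last] = True
    return m
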