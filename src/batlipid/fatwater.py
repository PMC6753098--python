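"""Multi-echo gradient-echo handling and fat-water separation.

The voxel signal model for a multi-echo gradient-echo acquisition is

    S(TE) = (W + F * sum_p alpha_p * exp(i 2 pi df_p TE))
            * exp(i 2 pi psi TE) * exp(-R2* TE)

with water amplitude ``W``, fat amplitude ``F`` spread over a multi-peak
spectrum (relative amplitudes ``alpha_p`` at frequency offsets ``df_p`` from
water), field-map off-resonance ``psi`` (Hz) and a common transverse decay
rate ``R2*`` (1/s).  Fat-signal fraction is ``FSF = 100 * F / (F + W)``.

Separation is performed per voxel by variable projection: for a candidate
(psi, R2*) the complex amplitudes (W, F) enter linearly and are projected
out, leaving a residual that is minimized over a bounded psi grid, followed
by spatially coherent candidate selection (region growing from a robust
seed) to avoid fat-water swaps, and local refinement of (psi, R2*).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GYROMAGNETIC_MHZ_PER_T",
    "EchoSchedule",
    "EchoSeries",
    "FatSpectrum",
    "FSFVolume",
    "SeparationOptions",
    "SeparationResult",
    "build_echo_schedule",
    "drop_leading_train_echoes",
    "separate_fat_water",
    "compute_fsf_map",
]

GYROMAGNETIC_MHZ_PER_T = 42.577478518
#: Proton Larmor frequency at 3 T (MHz).
F0_3T_MHZ = 3.0 * GYROMAGNETIC_MHZ_PER_T

# Published triglyceride spectrum (adipose/marrow type), chemical shifts on
# the TMS scale with water at 4.70 ppm.  Seven resolvable peaks; amplitudes
# are relative proton densities normalized to 1.
_SEVEN_PEAK_PPM = (5.31, 2.75, 2.24, 2.02, 1.60, 1.30, 0.90)
_SEVEN_PEAK_AMPS = (0.092, 0.015, 0.066, 0.083, 0.057, 0.598, 0.089)
_WATER_PPM = 4.70


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak spectral fat model.

    Parameters
    ----------
    rel_amplitudes
        Relative peak amplitudes, must sum to 1 (within 1e-12).
    freq_offsets_hz
        Peak frequency offsets relative to water, in Hz (negative =
        upfield of water at 3 T for the dominant methylene peak).
    """

    rel_amplitudes: tuple[float, ...]
    freq_offsets_hz: tuple[float, ...]

    def __post_init__(self) -> None:
        a = np.asarray(self.rel_amplitudes, dtype=float)
        f = np.asarray(self.freq_offsets_hz, dtype=float)
        if a.shape != f.shape or a.ndim != 1 or a.size == 0:
            raise ValueError("amplitudes and offsets must be 1-D with equal length")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError(f"peak amplitudes must sum to 1, got {a.sum()!r}")
        if np.any(a < 0):
            raise ValueError("peak amplitudes must be nonnegative")

    @property
    def n_peaks(self) -> int:
        return len(self.rel_amplitudes)

    @classmethod
    def from_ppm(
        cls,
        ppm: Sequence[float],
        rel_amplitudes: Sequence[float],
        f0_mhz: float = F0_3T_MHZ,
        water_ppm: float = _WATER_PPM,
    ) -> "FatSpectrum":
        """Build a spectrum from chemical shifts in ppm (TMS scale)."""
        offs = tuple((p - water_ppm) * f0_mhz for p in ppm)
        amps = np.asarray(rel_amplitudes, dtype=float)
        amps = amps / amps.sum()
        return cls(tuple(amps), offs)

    @classmethod
    def seven_peak_3t(cls) -> "FatSpectrum":
        """Default seven-peak triglyceride model at 3 T."""
        return cls.from_ppm(_SEVEN_PEAK_PPM, _SEVEN_PEAK_AMPS)

    @classmethod
    def single_peak(cls, freq_offset_hz: float = -3.40 * F0_3T_MHZ) -> "FatSpectrum":
        """Single-peak (classic Dixon) model, mainly for tests."""
        return cls((1.0,), (float(freq_offset_hz),))

    def phasors(self, te_s: np.ndarray) -> np.ndarray:
        """Complex fat modulation ``c_k = sum_p alpha_p exp(i 2 pi df_p TE_k)``."""
        te = np.asarray(te_s, dtype=float)
        a = np.asarray(self.rel_amplitudes)
        f = np.asarray(self.freq_offsets_hz)
        return (a[None, :] * np.exp(2j * np.pi * f[None, :] * te[:, None])).sum(axis=1)


@dataclass(frozen=True)
class EchoSchedule:
    """Echo times (ms) with interleaved-train structure.

    ``train_index[k]`` gives the train owning echo ``k``; with ``n_trains``
    interleaved trains, train ``j`` owns echoes ``j, j + n_trains, ...`` of
    the acquired order.
    """

    te_ms: tuple[float, ...]
    n_trains: int
    train_index: tuple[int, ...]

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        if te.ndim != 1 or te.size == 0:
            raise ValueError("te_ms must be a non-empty 1-D sequence")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if len(self.train_index) != len(self.te_ms):
            raise ValueError("train_index must have one entry per echo")
        if self.n_trains < 1:
            raise ValueError("n_trains must be >= 1")
        present = set(self.train_index)
        if not present <= set(range(self.n_trains)):
            raise ValueError("train_index entries must lie in [0, n_trains)")

    @property
    def n_echoes(self) -> int:
        return len(self.te_ms)

    @property
    def te_s(self) -> np.ndarray:
        return np.asarray(self.te_ms, dtype=float) * 1e-3

    def train_lengths(self) -> np.ndarray:
        return np.bincount(np.asarray(self.train_index), minlength=self.n_trains)


def build_echo_schedule(
    n_echoes: int = 18,
    first_te_ms: float = 1.395,
    effective_spacing_ms: float = 0.737,
    n_trains: int = 3,
) -> EchoSchedule:
    """Arithmetic echo-time schedule split over interleaved trains.

    ``TE_k = first_te + (k - 1) * spacing`` for k = 1..n_echoes; train ``j``
    owns echoes ``j, j + n_trains, ...`` (0-based).  The default reproduces
    an 18-echo, 3x6-interleaved acquisition with first echo 1.395 ms and
    effective spacing 0.737 ms.
    """
    if n_echoes < 1:
        raise ValueError("n_echoes must be positive")
    if n_trains < 1 or n_echoes % n_trains != 0:
        raise ValueError(
            f"n_echoes ({n_echoes}) must be divisible by n_trains ({n_trains})"
        )
    if effective_spacing_ms <= 0 or first_te_ms <= 0:
        raise ValueError("echo times and spacing must be positive")
    te = tuple(first_te_ms + k * effective_spacing_ms for k in range(n_echoes))
    trains = tuple(k % n_trains for k in range(n_echoes))
    return EchoSchedule(te, n_trains, trains)


@dataclass
class EchoSeries:
    """Complex multi-echo volume with its echo schedule.

    ``data`` has shape ``(nx, ny, nz, n_echoes)`` (slice axis is axis 2).
    """

    data: np.ndarray
    schedule: EchoSchedule
    acquisition_index: int = 0
    timestamp_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D (nx, ny, nz, n_echoes)")
        if self.data.shape[-1] != self.schedule.n_echoes:
            raise ValueError("last data axis must match the echo schedule")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("echo data must be finite")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


def drop_leading_train_echoes(series: EchoSeries) -> EchoSeries:
    """Remove the first echo of every interleaved train.

    Discards the leading echo of each train (e.g. 18 -> 15 echoes for a
    3x6-interleaved schedule), a standard guard against eddy-current phase
    contamination of the first readout in each train.  Not idempotent: a
    second application drops the next echo of every train.
    """
    sched = series.schedule
    lengths = sched.train_lengths()
    if np.any(lengths[np.unique(sched.train_index)] < 2):
        raise ValueError("each train needs at least 2 echoes to drop its first")
    seen: set[int] = set()
    keep: list[int] = []
    for k, j in enumerate(sched.train_index):
        if j in seen:
            keep.append(k)
        else:
            seen.add(j)
    new_sched = EchoSchedule(
        tuple(sched.te_ms[k] for k in keep),
        sched.n_trains,
        tuple(sched.train_index[k] for k in keep),
    )
    return EchoSeries(
        series.data[..., keep],
        new_sched,
        acquisition_index=series.acquisition_index,
        timestamp_s=series.timestamp_s,
    )


@dataclass
class SeparationResult:
    """Per-voxel fat-water decomposition: W, F magnitudes, psi, R2*."""

    water: np.ndarray  # |W|, >= 0
    fat: np.ndarray  # |F|, >= 0
    field_map_hz: np.ndarray  # psi
    r2star: np.ndarray  # 1/s
    residual: np.ndarray  # sum of squared model residuals
    valid: np.ndarray  # voxels that were fitted
    first_echo_magnitude: np.ndarray


@dataclass
class FSFVolume:
    """Fat-signal fraction map (%) with a validity mask.

    Invalid voxels (background, failed or out-of-range fits) keep their raw
    value (possibly NaN) and are flagged in ``valid`` rather than zeroed.
    """

    fsf: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.fsf = np.asarray(self.fsf, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.fsf.shape != self.valid.shape:
            raise ValueError("fsf and valid must share a shape")
        vals = self.fsf[self.valid]
        if vals.size and (np.any(~np.isfinite(vals)) or vals.min() < 0 or vals.max() > 100):
            raise ValueError("valid voxels must have FSF in [0, 100]")

    @classmethod
    def from_raw(cls, fsf_raw: np.ndarray, base_valid: np.ndarray) -> "FSFVolume":
        """Flag erroneous separations (FSF < 0 or > 100, or non-finite)."""
        fsf_raw = np.asarray(fsf_raw, dtype=float)
        ok = np.isfinite(fsf_raw) & (fsf_raw >= 0) & (fsf_raw <= 100)
        return cls(fsf_raw, np.asarray(base_valid, bool) & ok)

    def copy(self) -> "FSFVolume":
        return FSFVolume(self.fsf.copy(), self.valid.copy())


@dataclass
class SeparationOptions:
    """Tuning knobs for the variable-projection separation.

    ``psi_halfwidth_hz=None`` bounds the field-map grid at 1.5x the Nyquist
    frequency of the mean echo spacing.  ``region_growing`` selects among
    per-voxel candidate minima by spatial coherence, suppressing fat-water
    swaps; switching it off takes the global per-voxel minimum.
    """

    psi_halfwidth_hz: float | None = None
    psi_step_hz: float = 8.0
    r2star_grid: tuple[float, ...] = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)
    region_growing: bool = True
    max_candidates: int = 3
    refine_rounds: int = 2
    refine_iters: int = 12
    magnitude_fit: bool = False
    min_magnitude_frac: float = 0.0
    voxel_chunk: int = 2048


class _VarproProblem:
    """Precomputed per-dataset quantities for fast residual evaluation.

    For a candidate (psi, R2*) the basis is ``a1 = e``, ``a2 = c * e`` with
    ``e_k = exp((i 2 pi psi - R2*) TE_k)``.  Since ``|e_k|`` depends only on
    R2*, the Gram matrix reduces to real decay-weighted sums, and the data
    projections need a single conjugated phasor array.
    """

    def __init__(self, X: np.ndarray, te: np.ndarray, c: np.ndarray) -> None:
        self.X = X
        self.te = te
        self.c = c
        self.Xc = X * c.conj()[None, :]  # for b2
        self.abs_c2 = (c * c.conj()).real
        self.total = np.einsum("nk,nk->n", X.conj(), X).real

    def solve(
        self, psi: np.ndarray, r2: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        te = self.te
        decay2 = np.exp((-2.0 * r2)[:, None] * te[None, :])  # |e|^2
        ec = np.exp((-2j * np.pi) * psi[:, None] * te[None, :])
        ec *= np.sqrt(decay2)  # conj(e)
        g11 = decay2 @ np.ones_like(te)
        g22 = decay2 @ self.abs_c2
        g12 = decay2 @ self.c  # sum |e|^2 c_k
        b1 = np.einsum("nk,nk->n", ec, self.X)
        b2 = np.einsum("nk,nk->n", ec, self.Xc)
        det = g11 * g22 - (g12 * g12.conj()).real
        tiny = 1e-14 * np.maximum(g11 * g22, 1e-300)
        ok = det > tiny
        det_safe = np.where(ok, det, 1.0)
        x1 = (g22 * b1 - g12 * b2) / det_safe
        x2 = (g11 * b2 - g12.conj() * b1) / det_safe
        # degenerate basis (collinear columns): water-only fit
        x1 = np.where(ok, x1, b1 / np.maximum(g11, 1e-300))
        x2 = np.where(ok, x2, 0.0)
        energy = (x1.conj() * b1 + x2.conj() * b2).real
        resid = np.maximum(self.total - energy, 0.0)
        return resid, x1, x2

    def residual(self, psi: np.ndarray, r2: np.ndarray) -> np.ndarray:
        return self.solve(psi, r2)[0]


def _varpro_residual(
    X: np.ndarray, te: np.ndarray, c: np.ndarray, psi: np.ndarray, r2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residual and complex amplitudes of the VARPRO fit at per-voxel (psi, r2)."""
    return _VarproProblem(X, te, c).solve(psi, r2)


def _grid_candidates(
    X: np.ndarray,
    te: np.ndarray,
    c: np.ndarray,
    psi_grid: np.ndarray,
    r2_grid: np.ndarray,
    max_candidates: int,
    chunk: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local minima of the VARPRO residual over the psi grid.

    Returns (cand_psi, cand_r2, cand_resid) each of shape (N, M), padded
    with +inf residuals / NaN psi where fewer minima exist.
    """
    n_vox = X.shape[0]
    n_psi, n_r2 = psi_grid.size, r2_grid.size
    # Orthonormal bases, stacked over the (psi, r2) grid.
    psi2 = np.repeat(psi_grid, n_r2)
    r22 = np.tile(r2_grid, n_psi)
    e = np.exp((2j * np.pi * psi2[:, None] - r22[:, None]) * te[None, :])
    a1 = e
    a2 = c[None, :] * e
    q1 = a1 / np.linalg.norm(a1, axis=1, keepdims=True)
    proj = np.einsum("gk,gk->g", q1.conj(), a2)
    a2o = a2 - proj[:, None] * q1
    n2 = np.linalg.norm(a2o, axis=1)
    deg = n2 < 1e-10 * np.linalg.norm(a2, axis=1)
    n2 = np.where(deg, 1.0, n2)
    q2 = np.where(deg[:, None], 0.0, a2o / n2[:, None])
    # Hermitian projections: conjugate the basis once, then a plain matmul
    B = np.concatenate([q1.conj(), q2.conj()], axis=0)  # (2*G, K)

    M = max_candidates
    cand_psi = np.full((n_vox, M), np.nan)
    cand_r2 = np.zeros((n_vox, M))
    cand_res = np.full((n_vox, M), np.inf)
    G = n_psi * n_r2
    for lo in range(0, n_vox, chunk):
        hi = min(lo + chunk, n_vox)
        Xc = X[lo:hi]
        total = np.einsum("nk,nk->n", Xc.conj(), Xc).real
        coef = B @ Xc.T  # (2G, n)
        energy = np.abs(coef[:G]) ** 2 + np.abs(coef[G:]) ** 2
        resid = np.maximum(total[None, :] - energy, 0.0)  # (G, n)
        resid = resid.reshape(n_psi, n_r2, hi - lo)
        r2_best = np.argmin(resid, axis=1)  # (n_psi, n)
        res_psi = np.take_along_axis(resid, r2_best[:, None, :], axis=1)[:, 0, :]
        # local minima along psi (endpoints included)
        left = np.vstack([np.full((1, hi - lo), np.inf), res_psi[:-1]])
        right = np.vstack([res_psi[1:], np.full((1, hi - lo), np.inf)])
        is_min = (res_psi <= left) & (res_psi < right)
        masked = np.where(is_min, res_psi, np.inf)
        order = np.argpartition(masked, kth=min(M, n_psi) - 1, axis=0)[:M]  # (M, n)
        sel_res = np.take_along_axis(masked, order, axis=0)
        sort2 = np.argsort(sel_res, axis=0)
        order = np.take_along_axis(order, sort2, axis=0)
        sel_res = np.take_along_axis(sel_res, sort2, axis=0)
        sel_psi = psi_grid[order]
        sel_r2i = np.take_along_axis(r2_best, order, axis=0)
        cand_psi[lo:hi] = np.where(np.isfinite(sel_res), sel_psi, np.nan).T
        cand_r2[lo:hi] = r2_grid[sel_r2i].T
        cand_res[lo:hi] = sel_res.T
    return cand_psi, cand_r2, cand_res


def _region_grow_select(
    cand_psi: np.ndarray,
    cand_r2: np.ndarray,
    cand_res: np.ndarray,
    magnitude: np.ndarray,
    fitted: np.ndarray,
    shape: tuple[int, int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Spatially coherent candidate selection.

    Starting from the strongest-magnitude voxel (whose global-minimum
    candidate is trusted), neighbours are visited in descending magnitude
    order; each picks the candidate field-map value closest to the mean of
    its already-assigned 6-neighbours.  Disconnected components restart
    from their own strongest voxel.
    """
    nx, ny, nz = shape
    n = nx * ny * nz
    psi = np.zeros(n)
    r2 = np.zeros(n)
    assigned = np.zeros(n, dtype=bool)
    has_cand = fitted & np.isfinite(cand_res[:, 0])
    strides = (ny * nz, nz, 1)

    def neighbours(idx: int):
        i, rem = divmod(idx, strides[0])
        j, k = divmod(rem, strides[1])
        if i > 0:
            yield idx - strides[0]
        if i < nx - 1:
            yield idx + strides[0]
        if j > 0:
            yield idx - strides[1]
        if j < ny - 1:
            yield idx + strides[1]
        if k > 0:
            yield idx - 1
        if k < nz - 1:
            yield idx + 1

    mag = np.where(has_cand, magnitude, -1.0)
    remaining = int(has_cand.sum())
    in_heap = np.zeros(n, dtype=bool)
    while remaining > 0:
        seed = int(np.argmax(np.where(assigned, -1.0, mag)))
        psi[seed] = cand_psi[seed, 0]
        r2[seed] = cand_r2[seed, 0]
        assigned[seed] = True
        remaining -= 1
        heap: list[tuple[float, int]] = []
        for nb in neighbours(seed):
            if has_cand[nb] and not assigned[nb]:
                heapq.heappush(heap, (-mag[nb], nb))
                in_heap[nb] = True
        while heap:
            _, v = heapq.heappop(heap)
            if assigned[v]:
                continue
            ref_sum = 0.0
            ref_n = 0
            for nb in neighbours(v):
                if assigned[nb]:
                    ref_sum += psi[nb]
                    ref_n += 1
            ref = ref_sum / max(ref_n, 1)
            cps = cand_psi[v]
            good = np.isfinite(cps)
            dist = np.where(good, np.abs(cps - ref), np.inf)
            pick = int(np.argmin(dist))
            psi[v] = cps[pick]
            r2[v] = cand_r2[v, pick]
            assigned[v] = True
            remaining -= 1
            for nb in neighbours(v):
                if has_cand[nb] and not assigned[nb] and not in_heap[nb]:
                    heapq.heappush(heap, (-mag[nb], nb))
                    in_heap[nb] = True
    return psi, r2


def _refine_coordinate(
    eval_fn,
    x: np.ndarray,
    f0: np.ndarray,
    step: float,
    n_iter: int,
    lo: float,
    hi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized safeguarded successive-parabolic 1-D descent."""
    s = np.full_like(x, float(step))
    for _ in range(n_iter):
        xm = np.clip(x - s, lo, hi)
        xp = np.clip(x + s, lo, hi)
        fm = eval_fn(xm)
        fp = eval_fn(xp)
        denom = fm - 2.0 * f0 + fp
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = 0.5 * s * (fm - fp) / denom
        fallback = np.where(fm < fp, -s, s)
        delta = np.where((denom > 0) & np.isfinite(delta), delta, fallback)
        delta = np.clip(delta, -s, s)
        xn = np.clip(x + delta, lo, hi)
        fn = eval_fn(xn)
        # accept the best of the four probes
        stack_x = np.stack([x, xm, xp, xn])
        stack_f = np.stack([f0, fm, fp, fn])
        best = np.argmin(stack_f, axis=0)
        x = np.take_along_axis(stack_x, best[None], axis=0)[0]
        f0 = np.take_along_axis(stack_f, best[None], axis=0)[0]
        s = s * 0.5
    return x, f0


def _separate_magnitude(
    X: np.ndarray, te: np.ndarray, c: np.ndarray, r2_grid: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Magnitude-only fit over an FSF x R2* grid (noise-bias experiments)."""
    mags = np.abs(X)  # (N, K)
    fsf = np.arange(0.0, 100.5, 0.5)
    f = fsf / 100.0
    shape_f = np.abs((1 - f)[:, None] + f[:, None] * c[None, :])  # (Nf, K)
    best_res = np.full(mags.shape[0], np.inf)
    best_f = np.zeros(mags.shape[0])
    best_r2 = np.zeros(mags.shape[0])
    best_a = np.zeros(mags.shape[0])
    for r2 in r2_grid:
        d = shape_f * np.exp(-r2 * te)[None, :]  # (Nf, K)
        dd = (d**2).sum(axis=1)  # (Nf,)
        md = mags @ d.T  # (N, Nf)
        amp = md / dd[None, :]
        res = (mags**2).sum(axis=1)[:, None] - amp * md
        j = np.argmin(res, axis=1)
        rbest = np.take_along_axis(res, j[:, None], axis=1)[:, 0]
        upd = rbest < best_res
        best_res = np.where(upd, rbest, best_res)
        best_f = np.where(upd, f[j], best_f)
        best_r2 = np.where(upd, r2, best_r2)
        best_a = np.where(upd, np.take_along_axis(amp, j[:, None], axis=1)[:, 0], best_a)
    W = best_a * (1 - best_f)
    F = best_a * best_f
    return W, F, best_r2, np.maximum(best_res, 0.0)


def separate_fat_water(
    series: EchoSeries,
    spectrum: FatSpectrum | None = None,
    options: SeparationOptions | None = None,
) -> SeparationResult:
    """Estimate (W, F, psi, R2*) per voxel from a multi-echo series.

    Requires at least 4 echoes.  All-zero voxels are flagged invalid and not
    fitted.  See :class:`SeparationOptions` for the search strategy.
    """
    spectrum = spectrum or FatSpectrum.seven_peak_3t()
    opts = options or SeparationOptions()
    sched = series.schedule
    if sched.n_echoes < 4:
        raise ValueError("fat-water separation requires at least 4 echoes")
    te = sched.te_s
    c = spectrum.phasors(te)
    shape = series.grid_shape
    X_all = series.data.reshape(-1, sched.n_echoes)
    mag0 = np.abs(X_all[:, 0]).reshape(shape)

    any_signal = np.abs(X_all).max(axis=1) > 0
    if opts.min_magnitude_frac > 0 and any_signal.any():
        robust = np.percentile(np.abs(X_all[any_signal, 0]), 99)
        any_signal &= np.abs(X_all[:, 0]) >= opts.min_magnitude_frac * robust
    fitted = any_signal
    W = np.zeros(X_all.shape[0])
    F = np.zeros(X_all.shape[0])
    psi = np.zeros(X_all.shape[0])
    r2 = np.zeros(X_all.shape[0])
    resid = np.zeros(X_all.shape[0])
    idx = np.flatnonzero(fitted)
    if idx.size:
        X = X_all[idx]
        r2_grid = np.asarray(opts.r2star_grid, dtype=float)
        if opts.magnitude_fit:
            Wf, Ff, r2f, rf = _separate_magnitude(X, te, c, r2_grid)
            W[idx], F[idx], r2[idx], resid[idx] = Wf, Ff, r2f, rf
        else:
            dte = float(np.mean(np.diff(te)))
            half = opts.psi_halfwidth_hz
            if half is None:
                half = 1.5 * (1.0 / (2.0 * dte))
            n_psi = max(int(round(2 * half / opts.psi_step_hz)) + 1, 5)
            psi_grid = np.linspace(-half, half, n_psi)
            cand_psi, cand_r2, cand_res = _grid_candidates(
                X, te, c, psi_grid, r2_grid, opts.max_candidates, opts.voxel_chunk
            )
            if opts.region_growing:
                cp = np.full((X_all.shape[0], cand_psi.shape[1]), np.nan)
                cr = np.zeros_like(cp)
                cres = np.full_like(cp, np.inf)
                cp[idx], cr[idx], cres[idx] = cand_psi, cand_r2, cand_res
                psi_sel, r2_sel = _region_grow_select(
                    cp, cr, cres, mag0.ravel(), fitted, shape
                )
                psi_v, r2_v = psi_sel[idx], r2_sel[idx]
            else:
                psi_v, r2_v = cand_psi[:, 0], cand_r2[:, 0]
            psi_v = np.where(np.isfinite(psi_v), psi_v, 0.0)

            r2_hi = float(r2_grid.max()) * 1.5 + 50.0
            f_cur = _varpro_residual(X, te, c, psi_v, r2_v)[0]
            psi_step = float(opts.psi_step_hz)
            r2_step = float(np.max(np.diff(r2_grid))) / 2.0 if r2_grid.size > 1 else 10.0
            for _ in range(opts.refine_rounds):
                psi_v, f_cur = _refine_coordinate(
                    lambda p: _varpro_residual(X, te, c, p, r2_v)[0],
                    psi_v, f_cur, psi_step, opts.refine_iters, -1e9, 1e9,
                )
                r2_v, f_cur = _refine_coordinate(
                    lambda r: _varpro_residual(X, te, c, psi_v, r)[0],
                    r2_v, f_cur, r2_step, opts.refine_iters, 0.0, r2_hi,
                )
                psi_step *= 0.25
                r2_step *= 0.25
            rf, x1, x2 = _varpro_residual(X, te, c, psi_v, r2_v)
            W[idx] = np.abs(x1)
            F[idx] = np.abs(x2)
            psi[idx] = psi_v
            r2[idx] = r2_v
            resid[idx] = rf
    return SeparationResult(
        water=W.reshape(shape),
        fat=F.reshape(shape),
        field_map_hz=psi.reshape(shape),
        r2star=r2.reshape(shape),
        residual=resid.reshape(shape),
        valid=fitted.reshape(shape),
        first_echo_magnitude=mag0,
    )


def compute_fsf_map(
    result: SeparationResult, background_threshold_frac: float = 0.05
) -> FSFVolume:
    """Fat-signal fraction map with dominant-signal convention.

    Water-dominant voxels use ``100 * F / (F + W)``; fat-dominant voxels use
    ``100 * (1 - W / (F + W))`` (algebraically identical, but computed from
    the weaker species to limit noise bias under magnitude options).
    Background voxels — first-echo magnitude below
    ``background_threshold_frac`` times the 99th-percentile magnitude — are
    flagged invalid, as are voxels where ``F + W = 0``.
    """
    if not (0 <= background_threshold_frac < 1):
        raise ValueError("background_threshold_frac must be in [0, 1)")
    W, F = result.water, result.fat
    tot = W + F
    valid = result.valid & (tot > 0) & np.isfinite(tot)
    mag0 = result.first_echo_magnitude
    if valid.any() and background_threshold_frac > 0:
        robust = np.percentile(mag0[valid], 99)
        valid &= mag0 >= background_threshold_frac * robust
    with np.errstate(divide="ignore", invalid="ignore"):
        water_dom = 100.0 * F / tot
        fat_dom = 100.0 * (1.0 - W / tot)
        fsf = np.where(W >= F, water_dom, fat_dom)
    fsf = np.where(valid, fsf, np.nan)
    return FSFVolume.from_raw(fsf, valid)
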