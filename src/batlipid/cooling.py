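"""Cold-stress quantification: body surface area, cooling dose, log sync.

Cooling dose is the time integral of the relative water temperature
``T0 - T(t)`` (thermoneutral minus blanket water temperature) in degC*min;
normalized cooling dose divides by DuBois body surface area, giving
degC*min*m^-2, so that personalized protocols of different duration,
temperature and body size become comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Anthropometrics",
    "CoolingProfile",
    "SensationLog",
    "dubois_bsa",
    "cooling_dose",
    "normalized_cooling_dose",
    "sync_logs",
]


def dubois_bsa(mass_kg: float, height_cm: float) -> float:
    """DuBois & DuBois body surface area (m^2).

    ``BSA = 0.007184 * mass^0.425 * height^0.725`` with mass in kg and
    height in cm.
    """
    if mass_kg <= 0 or height_cm <= 0:
        raise ValueError("mass and height must be positive")
    return 0.007184 * mass_kg**0.425 * height_cm**0.725


@dataclass
class Anthropometrics:
    mass_kg: float
    height_cm: float

    def __post_init__(self) -> None:
        if self.mass_kg <= 0 or self.height_cm <= 0:
            raise ValueError("mass and height must be positive")

    @property
    def bsa_m2(self) -> float:
        return dubois_bsa(self.mass_kg, self.height_cm)


@dataclass
class CoolingProfile:
    """Timestamped blanket water temperatures with thermoneutral reference.

    ``time_min`` must be strictly increasing; ``thermoneutral_c`` is T0 in
    the relative-temperature integrand T0 - T(t).
    """

    time_min: np.ndarray
    set_temp_c: np.ndarray
    actual_temp_c: np.ndarray
    thermoneutral_c: float

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.set_temp_c = np.asarray(self.set_temp_c, dtype=float)
        self.actual_temp_c = np.asarray(self.actual_temp_c, dtype=float)
        if not (self.time_min.shape == self.set_temp_c.shape == self.actual_temp_c.shape):
            raise ValueError("time and temperature arrays must share a shape")
        if self.time_min.ndim != 1 or self.time_min.size == 0:
            raise ValueError("profile must contain at least one sample")
        if self.time_min.size > 1 and np.any(np.diff(self.time_min) <= 0):
            raise ValueError("sample times must be strictly increasing")

    @property
    def span_min(self) -> tuple[float, float]:
        return float(self.time_min[0]), float(self.time_min[-1])


@dataclass
class SensationLog:
    """Thermal sensation on the 0 (Very Cold) to 50 (Neutral) integer scale."""

    time_min: np.ndarray
    sensation: np.ndarray

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.sensation = np.asarray(self.sensation)
        if self.time_min.shape != self.sensation.shape or self.time_min.ndim != 1:
            raise ValueError("time and sensation must be 1-D with equal length")
        if self.sensation.size and (self.sensation.min() < 0 or self.sensation.max() > 50):
            raise ValueError("sensation values must lie in [0, 50]")


def cooling_dose(
    profile: CoolingProfile,
    t1: float,
    t2: float,
    use_actual: bool = True,
    relative_floor: float | None = None,
) -> float:
    """Trapezoidal integral of T0 - T(t) over [t1, t2] in degC*min.

    Uses the actual (measured) water temperature by default.  With the
    default ``relative_floor=None`` the integrand is signed, so re-warming
    above thermoneutral subtracts from the dose; a floor of 0 clamps it.
    """
    lo, hi = profile.span_min
    if not (lo <= t1 < t2 <= hi):
        raise ValueError(f"[t1, t2] = [{t1}, {t2}] outside profile span [{lo}, {hi}]")
    temp = profile.actual_temp_c if use_actual else profile.set_temp_c
    inner = profile.time_min[(profile.time_min > t1) & (profile.time_min < t2)]
    times = np.concatenate([[t1], inner, [t2]])
    vals = np.interp(times, profile.time_min, temp)
    rel = profile.thermoneutral_c - vals
    if relative_floor is not None:
        rel = np.maximum(rel, relative_floor)
    return float(np.trapezoid(rel, times))


def normalized_cooling_dose(
    profile: CoolingProfile, bsa_m2: float, t1: float, t2: float, **kwargs
) -> float:
    """Cooling dose divided by body surface area (degC*min*m^-2)."""
    if bsa_m2 <= 0:
        raise ValueError("body surface area must be positive")
    return cooling_dose(profile, t1, t2, **kwargs) / bsa_m2


def sync_logs(
    profile: CoolingProfile,
    sensation: SensationLog,
    acquisition_timestamps_min,
    bsa_m2: float | None = None,
    scan_duration_s: float = 115.7,
    **dose_kwargs,
) -> pd.DataFrame:
    """Synchronize cooling and sensation logs to image acquisition times.

    ``acquisition_timestamps_min`` are scan *start* times on the log clock;
    the reference instant for each acquisition is the scan midpoint
    (start + scan_duration / 2).  For each acquisition the cumulative dose
    from the start of the log to the reference instant and the most recent
    sensation value at or before it are reported.
    """
    ts = np.asarray(acquisition_timestamps_min, dtype=float)
    if ts.ndim != 1 or ts.size == 0:
        raise ValueError("need at least one acquisition timestamp")
    if ts.size > 1 and np.any(np.diff(ts) <= 0):
        raise ValueError("acquisition timestamps must be strictly increasing")
    lo, hi = profile.span_min
    mid = ts + scan_duration_s / 2.0 / 60.0
    if mid[0] < lo:
        raise ValueError("first acquisition precedes the start of the cooling log")
    if mid[-1] > hi:
        raise ValueError("acquisition reference time beyond the end of the cooling log")
    doses = np.array(
        [0.0 if m <= lo else cooling_dose(profile, lo, m, **dose_kwargs) for m in mid]
    )
    sens = np.empty(ts.size)
    for i, m in enumerate(mid):
        j = np.searchsorted(sensation.time_min, m, side="right") - 1
        if j < 0:
            raise ValueError("acquisition precedes the start of the sensation log")
        sens[i] = sensation.sensation[j]
    out = pd.DataFrame(
        {
            "acquisition": np.arange(1, ts.size + 1),
            "time_min": mid,
            "cum_dose": doses,
            "sensation": sens,
        }
    )
    if bsa_m2 is not None:
        if bsa_m2 <= 0:
            raise ValueError("body surface area must be positive")
        out["cum_norm_dose"] = out["cum_dose"] / bsa_m2
    return out
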