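"""Accumulated degree-days, insect age estimation and model validation.

Thermal summation turns a temperature history into accumulated
degree-days, ADD = ∫ max(0, T(t) − T_min) dt (°C·days).  A landmark is
predicted to occur when ADD reaches the thermal constant K of its fitted
model, which makes age (and hence minimum post-mortem interval)
estimation the inverse of accumulation.  Validation compares each reared
specimen's *actual* thermal units, D_observed · (T − T_min), with the
model constant K: relative error = |actual − K| / actual.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import (
    LANDMARKS,
    DevelopmentRecord,
    ValidationError,
)
from .linear import LinearFit

log = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class TemperatureProfile:
    """Time-stamped temperature series, piecewise constant between samples.

    ``times_h`` are hours from the reference point (strictly increasing);
    each temperature holds from its timestamp until the next.  The first
    temperature also covers any gap between time zero and the first sample.
    """

    times_h: np.ndarray
    temps_C: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times_h, float)
        x = np.asarray(self.temps_C, float)
        if t.size == 0:
            raise ValidationError("empty temperature profile")
        if t.size != x.size:
            raise ValidationError("times and temperatures differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("profile times must be strictly increasing")
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "temps_C", x)

    @classmethod
    def constant(cls, temperature: float, duration_h: float) -> "TemperatureProfile":
        return cls(np.array([0.0, duration_h]), np.array([temperature, temperature]))

    @classmethod
    def from_csv(cls, source, *, delimiter: str = ",") -> "TemperatureProfile":
        frame = pd.read_csv(source, sep=delimiter)
        cols = list(frame.columns[:2])
        return cls(frame[cols[0]].to_numpy(float), frame[cols[1]].to_numpy(float))

    @property
    def span_h(self) -> float:
        return float(self.times_h[-1])


def accumulate_ADD(
    profile: TemperatureProfile,
    T_min: float,
    horizon_h: float | None = None,
    *,
    trapezoid: bool = False,
) -> float:
    """Accumulated degree-days above T_min over [0, horizon] (°C·days).

    The profile is read as a step function (``trapezoid=True`` switches to
    linear interpolation between samples).  A horizon beyond the last
    sample extends the final temperature with a warning.
    """
    t = profile.times_h
    x = profile.temps_C
    if horizon_h is None:
        horizon_h = float(t[-1])
    if horizon_h < 0:
        raise ValidationError("horizon must be non-negative")
    if horizon_h > t[-1]:
        warnings.warn(
            f"horizon {horizon_h:.1f} h beyond profile span {t[-1]:.1f} h; "
            "extending the last temperature",
            stacklevel=2,
        )
        t = np.append(t, horizon_h)
        x = np.append(x, x[-1])
    # leading gap: first temperature holds from time zero
    if t[0] > 0:
        t = np.insert(t, 0, 0.0)
        x = np.insert(x, 0, x[0])

    add = 0.0
    for i in range(len(t) - 1):
        lo, hi = t[i], min(t[i + 1], horizon_h)
        if hi <= lo:
            break
        if trapezoid:
            frac = 0.0 if t[i + 1] == t[i] else (hi - t[i]) / (t[i + 1] - t[i])
            x_hi = x[i] + (x[i + 1] - x[i]) * frac
            # average of the clipped excess at the interval ends
            e_lo, e_hi = max(0.0, x[i] - T_min), max(0.0, x_hi - T_min)
            add += 0.5 * (e_lo + e_hi) * (hi - lo) / HOURS_PER_DAY
        else:
            add += max(0.0, x[i] - T_min) * (hi - lo) / HOURS_PER_DAY
    return add


def estimate_age(profile: TemperatureProfile, fit: LinearFit) -> float:
    """Smallest time (hours) at which accumulated degree-days reach fit.K.

    Inverse of :func:`accumulate_ADD` under the step interpretation, by
    linear interpolation within the straddling constant-temperature
    interval.  Raises when the profile never accumulates K.
    """
    t = profile.times_h
    x = profile.temps_C
    if t[0] > 0:
        t = np.insert(t, 0, 0.0)
        x = np.insert(x, 0, x[0])
    target = fit.K
    add = 0.0
    for i in range(len(t) - 1):
        rate = max(0.0, x[i] - fit.T_min) / HOURS_PER_DAY  # degree-days per hour
        step = rate * (t[i + 1] - t[i])
        if add + step >= target:
            if rate == 0:
                return float(t[i + 1])
            return float(t[i] + (target - add) / rate)
        add += step
    raise ValidationError(
        f"insufficient thermal input: profile accumulates {add:.2f} degree-days "
        f"but the model requires K = {target:.2f}"
    )


@dataclass(frozen=True)
class ValidationResult:
    landmark: str
    specimen_id: str
    group: str
    actual_ADD: float
    model_K: float
    relative_error: float


def validate(
    records: Sequence[DevelopmentRecord],
    fit: LinearFit,
    landmark: str,
    *,
    group_by: str = "temperature",
) -> tuple[list[ValidationResult], pd.DataFrame]:
    """Relative error of thermal units for each validation specimen.

    For each record that reached the landmark, actual thermal units are
    D_observed · (T − T_min); the relative error is |actual − K| / actual.
    The validation sample must be disjoint from the fitting sample — that
    is the caller's responsibility.  Returns per-specimen results and a
    per-group summary (mean, SE, n) grouped by temperature or diet.
    """
    if landmark not in LANDMARKS:
        raise ValidationError(f"unknown landmark {landmark!r}")
    results = []
    for rec in records:
        d = rec.landmark_time(landmark)
        if d is None:
            log.info("specimen %s skipped: landmark %s not reached", rec.specimen_id, landmark)
            continue
        actual = d * (rec.temperature - fit.T_min)
        if actual <= 0:
            log.warning(
                "specimen %s skipped: no thermal accumulation above threshold",
                rec.specimen_id,
            )
            continue
        group = str(rec.temperature) if group_by == "temperature" else str(rec.diet)
        results.append(
            ValidationResult(
                landmark=landmark,
                specimen_id=rec.specimen_id,
                group=group,
                actual_ADD=actual,
                model_K=fit.K,
                relative_error=abs(actual - fit.K) / actual,
            )
        )
    if results:
        frame = pd.DataFrame([r.__dict__ for r in results])
        summary = (
            frame.groupby("group")["relative_error"]
            .agg(["mean", "sem", "count"])
            .reset_index()
            .rename(columns={"mean": "mean_error", "sem": "se_error", "count": "n"})
        )
        summary["se_error"] = summary["se_error"].fillna(0.0)
    else:
        summary = pd.DataFrame(columns=["group", "mean_error", "se_error", "n"])
    return results, summary


def _tukey_hinges(sorted_values: np.ndarray) -> tuple[float, float, float]:
    """(Q1, median, Q3) with the median-inclusive (Tukey hinge) convention:
    for odd n the median belongs to both halves."""
    n = len(sorted_values)
    med = float(np.median(sorted_values))
    if n == 1:
        return med, med, med
    half = (n + 1) // 2  # inclusive of the median when n is odd
    q1 = float(np.median(sorted_values[:half]))
    q3 = float(np.median(sorted_values[n - half:]))
    return q1, med, q3


def isomorphen_data(records: Sequence[DevelopmentRecord]) -> pd.DataFrame:
    """Medians and interquartile ranges of landmark times per temperature.

    The plot-ready table behind an isomorphen diagram: one row per
    (temperature, landmark) with the median days from oviposition and the
    quartiles (median-inclusive convention).  Empty cells are omitted.
    """
    rows = []
    by_temp: dict[float, list[DevelopmentRecord]] = {}
    for rec in records:
        by_temp.setdefault(rec.temperature, []).append(rec)
    for temp in sorted(by_temp):
        for landmark in LANDMARKS:
            times = [
                t for r in by_temp[temp] if (t := r.landmark_time(landmark)) is not None
            ]
            if not times:
                continue
            arr = np.sort(np.asarray(times, float))
            q1, med, q3 = _tukey_hinges(arr)
            rows.append(
                {
                    "temperature_C": temp,
                    "landmark": landmark,
                    "median_d": float(med),
                    "q1_d": float(q1),
                    "q3_d": float(q3),
                    "n": len(arr),
                }
            )
    return pd.DataFrame(rows, columns=["temperature_C", "landmark", "median_d", "q1_d", "q3_d", "n"])
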