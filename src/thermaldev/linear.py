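"""Thermal summation model fitted by reduced-major-axis regression.

The model writes accumulated thermal units as a line in the duration of
development D (days) at constant temperature T (°C):

    D·T = K + T_min · D

so that the intercept K is the thermal summation constant (degree-days
above the threshold needed to reach the landmark) and the slope is the
lower developmental threshold T_min (°C).  Because both axes, D and D·T,
carry sampling error, the recommended estimator is the reduced major axis
(standard major axis): slope = sign(r)·sd(y)/sd(x).  Ordinary least
squares on the same axes is available for diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from .dataset import LandmarkDataset, ValidationError


@dataclass(frozen=True)
class LinearFit:
    """Fitted thermal summation line for one developmental landmark."""

    landmark: str
    K: float  # thermal summation constant, degree-days
    K_se: float
    T_min: float  # lower developmental threshold, °C
    T_min_se: float
    r2: float
    n: int
    temperature_range: tuple[float, float]
    method: str = "RMA"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def fit_thermal_summation(data: LandmarkDataset, method: str = "RMA") -> LinearFit:
    """Fit D·T = K + T_min·D to per-temperature mean durations.

    ``method`` is ``"RMA"`` (standard major axis, the recommended
    model-II estimator) or ``"OLS"`` (diagnostic).  Points are unweighted:
    one aggregate mean per temperature.

    Standard errors follow the conventional SMA expressions:
    SE(slope) = |slope|·sqrt((1−r²)/(n−2)) and the matching intercept SE.
    """
    data.validate()
    if method not in ("RMA", "OLS"):
        raise ValueError(f"unknown method {method!r}")
    x = data.durations  # D
    T = data.temperatures
    y = x * T  # DT, thermal units
    n = len(x)
    if n < 3:
        raise ValidationError(f"need >= 3 temperature points, got {n}")
    if np.ptp(x) == 0:
        raise ValidationError("zero variance in D")

    sx = float(np.std(x, ddof=1))
    sy = float(np.std(y, ddof=1))
    r = float(np.corrcoef(x, y)[0, 1])
    r2 = r * r
    if r < 0:
        raise ValidationError(
            "development rate decreases with temperature over the whole range; "
            "a thermal summation fit is not meaningful here"
        )
    if method == "RMA":
        slope = math.copysign(sy / sx, r)
    else:
        slope = r * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))

    # conventional SMA uncertainty; for OLS the same expressions are a
    # close upper bound and keep the result structure uniform
    slope_se = abs(slope) * math.sqrt(max(0.0, 1.0 - r2) / (n - 2))
    vy = sy * sy
    vx = sx * sx
    intercept_se = math.sqrt(
        vy * (1.0 - r2) * (n - 1) / (n - 2)
        * (1.0 / n + np.mean(x) ** 2 / ((n - 1) * vx))
    )
    return LinearFit(
        landmark=data.landmark,
        K=intercept,
        K_se=float(intercept_se),
        T_min=float(slope),
        T_min_se=float(slope_se),
        r2=r2,
        n=n,
        temperature_range=(float(T.min()), float(T.max())),
        method=method,
    )


def predict_duration(fit: LinearFit, temperature: float) -> float:
    """Expected days to the landmark at a constant temperature: K/(T − T_min)."""
    if temperature <= fit.T_min:
        raise ValidationError(
            f"temperature {temperature} °C is at or below the developmental "
            f"threshold {fit.T_min:.3f} °C; no development accrues"
        )
    return fit.K / (temperature - fit.T_min)
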