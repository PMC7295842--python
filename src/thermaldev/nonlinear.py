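"""Empirical nonlinear development-rate curves and their fitting.

Three classic rate models relate development rate 1/D (1/day) to constant
temperature T (°C):

* Analytis:  1/D = a·(T − T_min)^n · (T_max − T)^m
* Brière-2:  1/D = a·(T − T_min) · (T_max − T)^(1/d)
* Lactin-2:  1/D = e^(p·T) − e^(p·T_max − (T_max − T)/ΔT) + λ

The first two vanish at both cardinal temperatures by construction; the
Lactin-2 curve crosses zero where its λ shift allows, so its thresholds
are found by root finding.  Fitting minimises the unweighted squared
error of rates with the Levenberg–Marquardt algorithm from a documented
multistart grid; data from a nearly linear rate–temperature relationship
can push T_max far above anything biologically meaningful, so every
result carries a plausibility flag (T_max > 45 °C or T_min < 0 °C).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from itertools import product

import lmfit
import numpy as np
from scipy import optimize

from .dataset import LandmarkDataset, ValidationError

MODELS = ("analytis", "briere2", "lactin2")

#: flag limits for biologically implausible cardinal temperatures
T_MAX_PLAUSIBLE = 45.0
T_MIN_PLAUSIBLE = 0.0


@dataclass(frozen=True)
class AnalytisParams:
    a: float
    n: float
    m: float
    T_min: float
    T_max: float

    def rate(self, T):
        T = np.asarray(T, float)
        inside = (T > self.T_min) & (T < self.T_max)
        r = np.zeros_like(T)
        Ti = T[inside]
        r[inside] = (
            self.a * (Ti - self.T_min) ** self.n * (self.T_max - Ti) ** self.m
        )
        return r if r.ndim else float(r)


@dataclass(frozen=True)
class Briere2Params:
    a: float
    d: float
    T_min: float
    T_max: float

    def rate(self, T):
        T = np.asarray(T, float)
        inside = (T > self.T_min) & (T < self.T_max)
        r = np.zeros_like(T)
        Ti = T[inside]
        r[inside] = self.a * (Ti - self.T_min) * (self.T_max - Ti) ** (1.0 / self.d)
        return r if r.ndim else float(r)

    @property
    def T_opt(self) -> float:
        """Closed-form optimum: (d·T_max + T_min)/(d + 1)."""
        return (self.d * self.T_max + self.T_min) / (self.d + 1.0)


@dataclass(frozen=True)
class Lactin2Params:
    p: float
    T_max: float
    delta_T: float
    lam: float

    def rate(self, T):
        """Raw curve value; may be negative (clip only for prediction)."""
        T = np.asarray(T, float)
        arg1 = np.clip(self.p * T, -700, 700)
        arg2 = np.clip(self.p * self.T_max - (self.T_max - T) / self.delta_T, -700, 700)
        r = np.exp(arg1) - np.exp(arg2) + self.lam
        return r if r.ndim else float(r)


PARAM_CLASSES = {
    "analytis": AnalytisParams,
    "briere2": Briere2Params,
    "lactin2": Lactin2Params,
}


@dataclass
class NonlinearFitResult:
    model: str
    params: AnalytisParams | Briere2Params | Lactin2Params
    sse: float
    r2: float
    aicc: float
    n: int
    converged: bool
    implausible: bool = False

    def to_json(self) -> str:
        d = {"model": self.model, "params": asdict(self.params)}
        for k in ("sse", "r2", "aicc", "n", "converged", "implausible"):
            d[k] = getattr(self, k)
        return json.dumps(d, indent=2)


def aicc(sse: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion on a least-squares fit.

    AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n − k − 1); finite only when
    n > k + 1.
    """
    if n <= k + 1 or sse <= 0:
        return math.inf
    return n * math.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


# module-level aliases for direct evaluation
def rate_analytis(params: AnalytisParams, T):
    return params.rate(T)


def rate_briere2(params: Briere2Params, T):
    return params.rate(T)


def rate_lactin2(params: Lactin2Params, T):
    return params.rate(T)


def _start_grid(model: str, data: LandmarkDataset) -> list[dict[str, float]]:
    rates = data.rates
    scale = float(rates.max())
    tspan = float(np.ptp(data.temperatures)) or 1.0
    starts = []
    if model == "analytis":
        for tmin, tmax in product((0.0, 5.0, 10.0), (33.0, 36.0, 40.0)):
            # normalise a so the curve peaks near the observed maximum rate
            mid = 0.5 * (tmin + tmax)
            denom = (mid - tmin) ** 1.0 * (tmax - mid) ** 1.0
            starts.append(
                {"a": scale / denom, "n": 1.0, "m": 1.0, "T_min": tmin, "T_max": tmax}
            )
    elif model == "briere2":
        for tmin, tmax in product((0.0, 5.0, 10.0), (33.0, 36.0, 40.0)):
            mid = 0.5 * (tmin + tmax)
            denom = (mid - tmin) * (tmax - mid) ** (1.0 / 3.0)
            starts.append({"a": scale / denom, "d": 3.0, "T_min": tmin, "T_max": tmax})
    elif model == "lactin2":
        for tmax in (33.0, 36.0, 40.0):
            p = math.log(1.0 + scale) / max(tmax, 1.0)
            for p0 in (0.5 * p, p, 0.005, 0.01):
                starts.append({"p": p0, "T_max": tmax, "delta_T": tspan / 4.0, "lam": -0.05})
    else:
        raise ValueError(f"unknown model {model!r}")
    return starts


def _residual_fn(model: str, T: np.ndarray, obs: np.ndarray):
    cls = PARAM_CLASSES[model]

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        p = cls(**{k: pars[k].value for k in pars})
        return np.asarray(p.rate(T), float) - obs

    return residual


def fit_nonlinear(
    model: str,
    data: LandmarkDataset,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_jitter: int = 3,
) -> NonlinearFitResult:
    """Least-squares fit of one rate model to per-temperature mean rates.

    Multistart Levenberg–Marquardt: a documented start grid plus
    ``n_jitter`` seeded ±20 % jitters of each start; the best SSE wins.
    An explicit ``init`` is added to the start list, so the result is
    never worse than a fit from the caller's own starting point.  No
    parameter bounds are applied unless ``bounds`` is given.
    """
    data.validate()
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    cls = PARAM_CLASSES[model]
    field_names = [f for f in cls.__dataclass_fields__]
    k = len(field_names)
    T = data.temperatures
    obs = data.rates
    n = len(T)
    if n < k + 1:
        raise ValidationError(f"{model} needs >= {k + 1} temperature points, got {n}")

    starts = _start_grid(model, data)
    if init is not None:
        starts.insert(0, dict(init))
    rng = np.random.default_rng(seed)
    jittered = []
    for s in starts:
        jittered.append(s)
        for _ in range(n_jitter):
            jittered.append(
                {key: v * (1 + rng.uniform(-0.2, 0.2)) for key, v in s.items()}
            )

    residual = _residual_fn(model, T, obs)
    best = None
    for start in jittered:
        pars = lmfit.Parameters()
        for name in field_names:
            lo, hi = (bounds or {}).get(name, (-np.inf, np.inf))
            pars.add(name, value=start[name], min=lo, max=hi)
        try:
            out = lmfit.minimize(residual, pars, method="leastsq")
        except Exception:
            continue
        sse = float(np.sum(np.square(out.residual)))
        if math.isfinite(sse) and (best is None or sse < best[0]):
            best = (sse, out)
    if best is None:
        raise ValidationError(f"all {model} starts failed to evaluate")

    sse, out = best
    params = cls(**{name: float(out.params[name].value) for name in field_names})
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    tmin, _, tmax = cardinal_temperatures_params(model, params)
    implausible = (tmax is not None and tmax > T_MAX_PLAUSIBLE) or (
        tmin is not None and tmin < T_MIN_PLAUSIBLE
    )
    return NonlinearFitResult(
        model=model,
        params=params,
        sse=sse,
        r2=r2,
        aicc=aicc(sse, n, k),
        n=n,
        converged=bool(out.success),
        implausible=bool(implausible),
    )


def _lactin2_roots(p: Lactin2Params) -> tuple[float | None, float, float | None]:
    """(T_min, T_opt, T_max) of the Lactin-2 curve by numeric search."""
    res = optimize.minimize_scalar(
        lambda t: -p.rate(t), bounds=(-20.0, p.T_max + 50.0), method="bounded"
    )
    t_opt = float(res.x)
    tmin = tmax = None
    if p.rate(t_opt) > 0:
        # upper root: the inactivation exponential dominates above the optimum
        hi = t_opt + 1.0
        while p.rate(hi) > 0 and hi < t_opt + 500:
            hi += 1.0
        if p.rate(hi) <= 0:
            tmax = float(optimize.brentq(p.rate, t_opt, hi))
        # lower root exists only when the curve dips below zero (lam < 0)
        lo = t_opt - 1.0
        while p.rate(lo) > 0 and lo > -273.0:
            lo -= 1.0
        if p.rate(lo) <= 0:
            tmin = float(optimize.brentq(p.rate, lo, t_opt))
    return tmin, t_opt, tmax


def cardinal_temperatures_params(model, params):
    """(T_min, T_opt, T_max) for a parameter set; None where undefined."""
    if model == "analytis":
        res = optimize.minimize_scalar(
            lambda t: -params.rate(t), bounds=(params.T_min, params.T_max), method="bounded"
        )
        return params.T_min, float(res.x), params.T_max
    if model == "briere2":
        return params.T_min, params.T_opt, params.T_max
    if model == "lactin2":
        return _lactin2_roots(params)
    raise ValueError(f"unknown model {model!r}")


def cardinal_temperatures(result: NonlinearFitResult):
    """Cardinal temperatures (T_min, T_opt, T_max) of a fitted model."""
    return cardinal_temperatures_params(result.model, result.params)
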