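"""Sharpe–Schoolfield–Ikemoto (SSI) thermodynamic development model.

The SSI model treats development as driven by one rate-controlling enzyme
that is reversibly inactivated at both temperature extremes.  With all
temperatures in Kelvin,

           ρ_φ (T/T_φ) · exp[ΔH_A/R · (1/T_φ − 1/T)]
    1/D = ─────────────────────────────────────────────────────────────
           1 + exp[ΔH_L/R · (1/T_L − 1/T)] + exp[ΔH_H/R · (1/T_H − 1/T)]

where ρ_φ is the development rate (1/day) at the intrinsic optimum T_φ
(the temperature at which no enzyme inactivation is hypothesised), ΔH_A
is the activation enthalpy of the catalysed reaction, ΔH_L < 0 and
ΔH_H > 0 the enthalpies of low- and high-temperature inactivation
(cal/mol), T_L and T_H the temperatures at which the enzyme is half
active and half inactivated at the respective extreme, and R the gas
constant, 1.987 cal/(deg·mol).

Identification
--------------
T_φ is by definition the temperature maximising the active-enzyme
fraction P(T) = 1/(1 + e^[ΔH_L/R(1/T_L − 1/T)] + e^[ΔH_H/R(1/T_H − 1/T)]);
setting dP/dT = 0 at T_φ ties the inactivation parameters together:

    ΔH_L·e^[ΔH_L/R(1/T_L − 1/T_φ)] + ΔH_H·e^[ΔH_H/R(1/T_H − 1/T_φ)] = 0.

On a ten-point rate curve the unconstrained family is still badly
over-flexible: unbounded least squares drives ΔH_H toward a step
function and parks T_H in the middle of the data, leaving T_φ
unidentified.  This module therefore fits the model the way it is used
in insect thermal biology:

* T_L is anchored at the lower developmental threshold T_min of the
  linear thermal summation fit to the same data (overridable).  The low
  tail of a development-rate curve carries little information of its
  own, and the linear threshold is the robust estimate of the same
  physical quantity — the two are expected to be congruent.
* ΔH_L is eliminated through the stationarity condition above (the
  real branch of the Lambert W function with |ΔH_L| large, the branch
  on which observed insect parameter sets lie).
* ΔH_A and ΔH_H are bounded to enzyme-kinetic magnitudes
  (5×10³–2×10⁵ cal/mol in absolute value), and T_H — the temperature of
  half high-temperature inactivation — may not sit below the warmest
  temperature at which development is still observed to accelerate
  (lower bound: data maximum − 0.5 °C).

Fitting is the nested optimisation the interface advertises: an outer
deterministic search over T_φ (grid across the data's temperature
range, golden-section refinement around the best grid point) with an
inner Levenberg–Marquardt least-squares fit of (ρ_φ, ΔH_A, ΔH_H, T_H)
at each fixed T_φ.  Temperatures are stored in °C to match the usual
reporting convention; every evaluation converts to Kelvin.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import lmfit
import numpy as np
from scipy.special import lambertw

from .dataset import LandmarkDataset, ValidationError
from .linear import LinearFit, fit_thermal_summation
from .nonlinear import aicc

#: gas constant, cal/(deg·mol) — fixed, never fitted
R_GAS = 1.987

_K0 = 273.15  # °C → K offset

#: enzyme-kinetic bounds on enthalpy magnitudes, cal/mol
DH_A_BOUNDS = (5e3, 1e5)
DH_H_BOUNDS = (5e3, 2e5)
DH_L_MAGNITUDE_MAX = 2e5


@dataclass(frozen=True)
class SSIParams:
    """SSI parameter set; temperatures stored in °C, enthalpies in cal/mol."""

    rho_phi: float  # development rate at the intrinsic optimum (1/day)
    dH_A: float  # activation enthalpy (cal/mol)
    dH_L: float  # low-T inactivation enthalpy (cal/mol, negative)
    dH_H: float  # high-T inactivation enthalpy (cal/mol, positive)
    T_phi: float  # intrinsic optimum (°C)
    T_L: float  # half low-inactivation temperature (°C)
    T_H: float  # half high-inactivation temperature (°C)

    def rate(self, T):
        return rate_ssi(self, T)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _guarded_exp(arg):
    return np.exp(np.clip(arg, -700.0, 700.0))


def rate_ssi(params: SSIParams, T):
    """Development rate (1/day) at temperature T (°C); non-negative.

    All temperature ratios use Kelvin; exponent arguments are clipped at
    ±700 so the function is total.
    """
    T = np.asarray(T, float)
    if np.any(T <= -_K0):
        raise ValidationError("temperature at or below absolute zero")
    TK = T + _K0
    Tphi = params.T_phi + _K0
    TL = params.T_L + _K0
    TH = params.T_H + _K0
    num = params.rho_phi * (TK / Tphi) * _guarded_exp(
        params.dH_A / R_GAS * (1.0 / Tphi - 1.0 / TK)
    )
    den = (
        1.0
        + _guarded_exp(params.dH_L / R_GAS * (1.0 / TL - 1.0 / TK))
        + _guarded_exp(params.dH_H / R_GAS * (1.0 / TH - 1.0 / TK))
    )
    r = np.maximum(num / den, 0.0)
    return r if r.ndim else float(r)


def intrinsic_optimum_residual(params: SSIParams) -> float:
    """Value of the stationarity condition at T_phi; 0 for a consistent set."""
    TphiK = params.T_phi + _K0
    return params.dH_L * math.exp(
        params.dH_L / R_GAS * (1.0 / (params.T_L + _K0) - 1.0 / TphiK)
    ) + params.dH_H * math.exp(
        params.dH_H / R_GAS * (1.0 / (params.T_H + _K0) - 1.0 / TphiK)
    )


def derive_T_L(dH_L: float, dH_H: float, T_H: float, T_phi: float) -> float:
    """T_L (°C) implied by the intrinsic-optimum condition at T_phi."""
    if not (dH_L < 0 < dH_H):
        raise ValidationError("intrinsic-optimum constraint needs dH_L < 0 < dH_H")
    TphiK = T_phi + _K0
    inv_TL = 1.0 / TphiK + (R_GAS / dH_L) * (
        math.log(-dH_H / dH_L) + dH_H / R_GAS * (1.0 / (T_H + _K0) - 1.0 / TphiK)
    )
    if inv_TL <= 0:
        raise ValidationError("constraint yields a non-physical T_L")
    return 1.0 / inv_TL - _K0


def derive_dH_L(dH_H: float, T_H: float, T_phi: float, T_L: float) -> float | None:
    """ΔH_L implied by the intrinsic-optimum condition, or None if infeasible.

    Solves ΔH_L·e^(a·ΔH_L) = b with a = (1/T_L − 1/T_φ)/R and
    b = −ΔH_H·e^[ΔH_H/R(1/T_H − 1/T_φ)] via the Lambert W branch −1,
    the branch carrying the large-magnitude (steep cold-inactivation)
    solutions observed for insect development.
    """
    if T_L >= T_phi:
        return None
    a = (1.0 / (T_L + _K0) - 1.0 / (T_phi + _K0)) / R_GAS  # > 0
    b = -dH_H * math.exp(
        np.clip(dH_H / R_GAS * (1.0 / (T_H + _K0) - 1.0 / (T_phi + _K0)), -700, 700)
    )
    ab = a * b
    if not -1.0 / math.e < ab < 0.0:
        return None
    w = lambertw(ab, -1)
    if abs(w.imag) > 1e-9:
        return None
    return float(w.real / a)


@dataclass
class SSIFitResult:
    params: SSIParams
    sse: float
    r2: float
    aicc: float
    n: int
    converged: bool
    boundary_warning: bool  # T_phi search collapsed to the search range edge

    def to_json(self) -> str:
        d = {"params": asdict(self.params)}
        for k in ("sse", "r2", "aicc", "n", "converged", "boundary_warning"):
            d[k] = getattr(self, k)
        return json.dumps(d, indent=2)


# parameter count for AICc: six reported parameters + error variance
_K_AICC = 7

_BIG = 1e6  # residual magnitude signalling an infeasible parameter point


def _params_at(pars, t_phi: float, t_l: float) -> SSIParams | None:
    dH_H = pars["dH_H"].value
    T_H = pars["T_H"].value
    dH_L = derive_dH_L(dH_H, T_H, t_phi, t_l)
    if dH_L is None or not -DH_L_MAGNITUDE_MAX <= dH_L < 0:
        return None
    return SSIParams(
        rho_phi=pars["rho_phi"].value,
        dH_A=pars["dH_A"].value,
        dH_L=dH_L,
        dH_H=dH_H,
        T_phi=t_phi,
        T_L=t_l,
        T_H=T_H,
    )


def _inner_fit(
    T: np.ndarray,
    obs: np.ndarray,
    t_phi: float,
    t_l: float,
    starts: list[dict[str, float]],
):
    """Best bounded LM fit of (rho_phi, dH_A, dH_H, T_H) at fixed T_phi, T_L."""
    t_data_max = float(T.max())

    def residual(pars: lmfit.Parameters) -> np.ndarray:
        p = _params_at(pars, t_phi, t_l)
        if p is None:
            return np.full_like(obs, _BIG)
        return np.asarray(rate_ssi(p, T), float) - obs

    best = None
    for start in starts:
        pars = lmfit.Parameters()
        pars.add("rho_phi", value=max(start["rho_phi"], 1e-6), min=1e-8)
        pars.add(
            "dH_A",
            value=float(np.clip(start["dH_A"], *DH_A_BOUNDS)),
            min=DH_A_BOUNDS[0],
            max=DH_A_BOUNDS[1],
        )
        pars.add(
            "dH_H",
            value=float(np.clip(start["dH_H"], *DH_H_BOUNDS)),
            min=DH_H_BOUNDS[0],
            max=DH_H_BOUNDS[1],
        )
        pars.add(
            "T_H",
            value=max(start["T_H"], t_data_max),
            min=t_data_max - 0.5,
            max=t_data_max + 10.0,
        )
        try:
            out = lmfit.minimize(residual, pars, method="leastsq")
        except Exception:
            continue
        sse = float(np.sum(np.square(out.residual)))
        params = _params_at(out.params, t_phi, t_l)
        if params is not None and math.isfinite(sse) and (
            best is None or sse < best[0]
        ):
            best = (sse, params, bool(out.success))
    if best is None:
        return math.inf, None, False
    return best


def _fresh_starts(
    data: LandmarkDataset, t_phi: float, rng: np.random.Generator, n_restarts: int
) -> list[dict[str, float]]:
    """Documented inner starts: enthalpies at typical insect magnitudes,
    T_H at the data range's warm end, rho_phi at the observed rate nearest
    the candidate optimum; ±20 % seeded jitter."""
    T = data.temperatures
    obs = data.rates
    rho0 = float(obs[np.argmin(np.abs(T - t_phi))])
    base = {
        "rho_phi": rho0,
        "dH_A": 19000.0,
        "dH_H": 42000.0,
        "T_H": float(T.max()),
    }
    starts = [dict(base)]
    for _ in range(n_restarts - 1):
        starts.append({k: v * (1 + rng.uniform(-0.2, 0.2)) for k, v in base.items()})
    return starts


def _warm_start(params: SSIParams) -> dict[str, float]:
    return {
        "rho_phi": params.rho_phi,
        "dH_A": params.dH_A,
        "dH_H": params.dH_H,
        "T_H": params.T_H,
    }


def fit_ssi(
    data: LandmarkDataset,
    t_phi_grid: float = 0.05,
    seed: int = 0,
    n_restarts: int = 5,
    t_l: float | None = None,
) -> SSIFitResult:
    """Nested fit of the SSI model to per-temperature mean rates.

    ``t_l`` fixes the half low-inactivation temperature; by default it is
    the lower developmental threshold of a linear thermal summation fit
    to the same data.  Outer search: T_φ on a grid of step ``t_phi_grid``
    (°C) from just above T_L to the data's warmest temperature,
    warm-starting each inner fit from the best neighbouring solution
    (with periodic fresh multistarts), then golden-section refinement
    around the best grid point.  Inner: multistart bounded
    Levenberg–Marquardt over (ρ_φ, ΔH_A, ΔH_H, T_H) with ΔH_L derived
    from the intrinsic-optimum constraint.  Deterministic for a given
    seed.
    """
    data.validate()
    T = data.temperatures
    obs = data.rates
    n = len(T)
    if n < 7:
        raise ValidationError(f"SSI fit needs >= 7 temperature points, got {n}")
    if t_l is None:
        t_l = fit_thermal_summation(data).T_min
    rng = np.random.default_rng(seed)

    lo = max(float(T.min()), t_l + 1.0)
    hi = float(T.max())
    if lo >= hi:
        raise ValidationError("no admissible T_phi range above T_L")
    grid = np.arange(lo, hi + 0.5 * t_phi_grid, t_phi_grid)

    best: tuple[float, SSIParams | None, bool] = (math.inf, None, False)
    warm: SSIParams | None = None
    for i, t_phi in enumerate(grid):
        starts = []
        if warm is not None:
            starts.append(_warm_start(warm))
        # periodic fresh multistarts guard against tracking a local valley
        if warm is None or i % 25 == 0:
            starts.extend(_fresh_starts(data, float(t_phi), rng, n_restarts))
        sse, params, ok = _inner_fit(T, obs, float(t_phi), t_l, starts)
        if params is not None:
            warm = params
            if sse < best[0]:
                best = (sse, params, ok)

    if best[1] is None:
        raise ValidationError("no inner SSI fit converged at any grid point")

    # golden-section refinement of T_phi around the best grid point
    anchor = _warm_start(best[1])

    def objective(t_phi: float):
        starts = [anchor] + _fresh_starts(data, t_phi, rng, 2)
        return _inner_fit(T, obs, t_phi, t_l, starts)

    a = max(lo, best[1].T_phi - t_phi_grid)
    b = min(hi, best[1].T_phi + t_phi_grid)
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    c, d_ = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = objective(c), objective(d_)
    for _ in range(20):
        if b - a < 1e-4:
            break
        if fc[0] < fd[0]:
            b, d_, fd = d_, c, fc
            c = b - invphi * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d_, fd
            d_ = a + invphi * (b - a)
            fd = objective(d_)
    for cand in (fc, fd):
        if cand[1] is not None and cand[0] < best[0]:
            best = cand

    sse, params, ok = best
    sst = float(np.sum((obs - obs.mean()) ** 2))
    boundary = bool(
        abs(params.T_phi - lo) < t_phi_grid / 2 or abs(params.T_phi - hi) < t_phi_grid / 2
    )
    return SSIFitResult(
        params=params,
        sse=sse,
        r2=1.0 - sse / sst if sst > 0 else float("nan"),
        aicc=aicc(sse, n, _K_AICC),
        n=n,
        converged=ok,
        boundary_warning=boundary,
    )


def linear_ssi_concordance(
    linear_fit: LinearFit, ssi_params: SSIParams, landmark: str | None = None
) -> float:
    """T_L (SSI) minus T_min (thermal summation) for the same landmark, °C.

    The two thresholds estimate the same physical quantity from different
    model families; this diagnostic reports their difference (zero by
    construction when the SSI fit anchored T_L to this linear fit).
    """
    if landmark is not None and linear_fit.landmark != landmark:
        raise ValidationError(
            f"linear fit is for {linear_fit.landmark!r}, expected {landmark!r}"
        )
    return float(ssi_params.T_L - linear_fit.T_min)
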