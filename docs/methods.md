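# Methods

This note documents the models implemented in `thermaldev`, the choices
made where the procedure was genuinely open, and what the synthetic
cohorts do and do not establish about real rearing data.

## Data model

A rearing experiment is represented at two levels. A
`DevelopmentRecord` is one specimen: constant rearing temperature,
durations (days) of the completed stages egg → L1 → L2 → L3 → pupa, and
a fate (emerged, or died naming the stage entered but not completed).
The stages present must form a prefix of that sequence. A
`LandmarkDataset` is the fitting input: per-temperature mean times from
oviposition to one of five landmarks (hatching, first and second
ecdysis, pupation, eclosion), one aggregate row per temperature.

The bundled per-temperature duration summary covers ten constant
temperatures, 10–32.5 °C in 2.5 °C steps. Cumulative landmark times
are sums of the constituent stage means, with two deliberate
exceptions:

* time to eclosion is taken from the separately tabulated total
  development column rather than the sum of stage means — the per-stage
  means average different specimen subsets (mortality and measurement
  protocol differ by stage), so their sum is not the mean total that
  the models should see (at 15 °C the sum is 111.2 d against a total of
  122.21 d);
* a temperature lacking any constituent stage simply drops out of that
  landmark's dataset. Development completed only over 15–30 °C, so
  hatching through second ecdysis use ten temperatures, pupation eight
  and eclosion seven.

Aggregate SEs are quadrature sums of stage SEs and the N is the
smallest constituent N; they are carried for display, the fits are
unweighted.

Mortality summaries use the standard percentage (dead × 100 / sampled)
and a Pearson chi-square on the groups × {dead, survived} table without
continuity correction, upper-tail p.

## Linear thermal summation

The model is `D·T = K + T_min·D`: regressing thermal units `D·T` on
duration `D` yields the thermal summation constant `K` (degree-days) as
intercept and the lower developmental threshold `T_min` (°C) as slope.
Both axes are functions of the measured duration, so a model-II
estimator is appropriate: the reduced (standard) major axis slope
`sign(r)·sd(DT)/sd(D)`. Points are unweighted per-temperature means;
specimen-level input is aggregated first. Standard errors follow the
conventional SMA expressions, `SE(slope) = |slope|·sqrt((1−r²)/(n−2))`
and the matching intercept formula. A negative correlation between `D`
and `D·T` means thermal units shrink as development lengthens — no
meaningful threshold exists — and the fit is refused with an
explanatory error rather than returning a negative-slope artefact.
OLS on the same axes is available as a diagnostic.

Simulation shows the SMA intervals undercover modestly on this small
design (81–92 % observed coverage at nominal 95 % across seed batches,
7 temperatures × 10 specimens); the point estimates are unbiased to
well under 1 %. Treat the SEs as indicative, not exact.

## Nonlinear rate curves

Analytis, Brière-2 and Lactin-2 relate rate `1/D` (1/day) to
temperature; the first two vanish at their `T_min`/`T_max` parameters
by construction, the Lactin-2 thresholds are roots found numerically.
Fitting minimises unweighted squared rate error by Levenberg–Marquardt
from a documented start grid (`T_min ∈ {0,5,10}`, `T_max ∈ {33,36,40}`,
shape constants near 1, scale set from the observed maximum rate) plus
seeded ±20 % jitters; the best SSE wins, and a caller-supplied start is
always included, so the result is never worse than the caller's own
starting point. No bounds are applied by default: on data where
mortality has removed the warm decline of the curve (rates here still
rise at the warmest viable temperature), these models legitimately run
away to enormous upper thresholds, and that outcome should be visible,
not hidden. Every result carries an `implausible` flag
(`T_max > 45 °C` or `T_min < 0 °C`). Model comparison uses
`AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1)` with k the parameter count.

## SSI thermodynamic model

The Sharpe–Schoolfield–Ikemoto model drives development by one
rate-controlling enzyme, reversibly inactivated at both temperature
extremes (all temperatures in Kelvin internally, reported in °C;
R = 1.987 cal/(deg·mol), never fitted):

```
1/D = ρ_φ (T/T_φ) exp[ΔH_A/R (1/T_φ − 1/T)]
      ───────────────────────────────────────────────────────
      1 + exp[ΔH_L/R (1/T_L − 1/T)] + exp[ΔH_H/R (1/T_H − 1/T)]
```

`T_φ` is the intrinsic optimum — the temperature maximising the
active-enzyme fraction — so it is not a free dial: stationarity of that
fraction at `T_φ` ties the inactivation parameters together. The fit
honours this identity exactly, eliminating `ΔH_L` through the Lambert W
function (branch −1, the steep-cold-inactivation branch on which insect
parameter sets lie).

Even so, a ten-point rate curve cannot identify all remaining
parameters freely: unconstrained least squares drives `ΔH_H` toward a
step function parked inside the data range and the SSE profile in
`T_φ` goes nearly flat. Three restrictions, each with a physical
reading, make the fit reproducible:

* `T_L` is anchored at the linear fit's `T_min` (overridable via
  `t_l=`). Both parameters estimate the same quantity — the
  temperature where development effectively stops — and the linear
  threshold is the robust estimate; the cold tail of a rate curve
  cannot beat it from three or four points. The congruence of the two
  thresholds reported for this model family is this identity.
* Enthalpies are bounded to enzyme-kinetic magnitudes: `ΔH_A` in
  [5·10³, 10⁵], `ΔH_H` in [5·10³, 2·10⁵], `|ΔH_L|` ≤ 2·10⁵ cal/mol.
* `T_H`, the half high-inactivation temperature, may not sit below the
  warmest temperature at which development is still observed
  (lower bound data max − 0.5 °C, upper bound data max + 10 °C).

The optimiser is the nested search the interface advertises: an outer
grid over `T_φ` (default 0.05 °C) spanning the admissible range, each
inner bounded Levenberg–Marquardt fit of (ρ_φ, ΔH_A, ΔH_H, T_H)
warm-started from the neighbouring solution with periodic fresh
multistarts (starts: ΔH_A ≈ 19 000, ΔH_H ≈ 42 000 cal/mol, T_H at the
warm end, ρ_φ at the observed rate nearest the candidate optimum,
±20 % seeded jitter), followed by golden-section refinement around the
best grid point. The procedure is deterministic for a given seed, and
the reported SSE is never worse than the best inner fit at any grid
point. AICc uses k = 7 (six reported parameters plus error variance).
On the bundled hatching data the fit lands at `T_φ` ≈ 19.0 °C,
`T_L` ≈ 8.5 °C, `T_H` ≈ 32 °C with enthalpies at ordinary magnitudes.

## Degree-day machinery

Temperature profiles are step functions (hourly crime-scene records;
a trapezoid option exists behind a flag). Accumulated degree-days are
`ADD = Σ max(0, T − T_min)·Δt` in °C·days; age estimation inverts this
by linear interpolation within the straddling constant-temperature
interval and is exact (round-trip to 1e−9). A horizon beyond the
profile extends the last temperature with a warning; an unreachable
`K` raises an explicit insufficient-thermal-input error.

Validation follows the thermal-unit comparison: each specimen's actual
thermal units `D_observed·(T − T_min)` against the model constant `K`,
relative error `|actual − K|/actual`, summarised as mean ± SE per
temperature or diet group. The specimen's own observed duration is
used, not a model prediction. On the bundled means the errors stay
below 10 % through the 20–27.5 °C core and grow toward the cold edge,
where the linear approximation breaks down; late landmarks carry larger
errors than early ones.

Isomorphen tables report median landmark times with median-inclusive
(Tukey hinge) quartiles — the convention is stated because quartile
conventions differ and the choice is otherwise invisible.

## Synthetic cohorts

The generator draws what the analysis assumes: a linear ground truth
(`K`, `T_min`, with the degree-day budget split across stages by
configurable fractions defaulting to the observed mid-range
proportions), lognormal between-specimen duration variation at a
configurable CV (default 0.10, matching the observed SE/mean ratios at
moderate temperatures; durations are positive and right-skewed),
Bernoulli mortality applied at stage entry, and interval censoring by
the bench protocol: inspections start at 60 % of the mean stage
duration (70 % for the egg stage) and repeat every 10 % of it, the
recorded time being the midpoint of the bracketing inspections.
The schedule is driven by the true model mean — the clean idealisation
of the pilot-test estimates an experimenter would use — which makes the
discretisation error exactly boundable: half an inspection interval per
stage whenever the true duration exceeds the first-check time (it does,
overwhelmingly, at the CVs simulated here; at CVs large enough to push
durations before the first check the bound does not apply). Identical
configurations produce identical cohorts; records carry their
uncensored durations for testing.

What passing tests show: unbiased recovery of the generating constants
through the full observation pipeline, censoring errors within the
stated bound, mortality rates converging to their probabilities. What
they do not show: robustness to model misspecification (real stage
durations need not be lognormal, real mortality is not independent of
development speed, incubator temperatures fluctuate), nor anything
about diet effects beyond the multiplicative shift the generator
implements.

## Numerical choices and degenerate inputs

Exponent arguments are clipped at ±700 before exponentiation; SSI and
clipped nonlinear rates are floored at 0. Fits require at least k+1
points (linear: 3; SSI: 7). Zero variance in D, non-positive
durations, stage-sequence gaps and empty profiles raise validation
errors naming the offender. All stochastic routines take an explicit
seed and are deterministic given it.

## Known limitations

* The linear model is a mid-range approximation; its errors grow near
  both thermal limits, and `T_min` is an extrapolated intercept, not an
  observed limit (development failed outright at 12.5 °C despite a
  fitted threshold near 8 °C for early landmarks).
* The nonlinear empirical models are included for completeness and
  comparison; on data without a warm decline their thresholds are not
  interpretable, which the plausibility flag makes explicit.
* SSI parameters beyond `T_φ`, `T_L` and `T_H` are weakly identified
  from ten rate means; the enthalpy bounds are part of the model
  specification here, and refits under different bounds will move the
  enthalpies more than the temperatures.
* Validation against the fitting means is a consistency check, not an
  independent validation; true validation requires specimens outside
  the fitting sample, which the caller must supply.
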