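"""Synthetic rearing cohorts with a known ground truth.

The generator emulates a constant-temperature rearing experiment: a true
development model gives the mean duration of each stage at each
temperature, individual specimens scatter around those means
(lognormal, fixed coefficient of variation), each stage is entered
alive only with the configured survival probability, and landmark times
are observed through the inspection protocol used at the bench — checks
start at 60 % of the mean stage duration (70 % for the egg stage) and
repeat every 10 % of it, the recorded time being the midpoint of the
bracketing inspections.  Because the truth is known, fitting and
validation code can be tested for parameter recovery and the censoring
error can be bounded exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dataset import STAGES, DevelopmentRecord, ValidationError
from .linear import LinearFit

#: default split of total development time across stages, the observed
#: proportions at a mid-range rearing temperature (egg, L1, L2, L3, pupa)
DEFAULT_STAGE_FRACTIONS: dict[str, float] = {
    "egg": 0.0929,
    "L1": 0.0612,
    "L2": 0.0764,
    "L3": 0.4544,
    "pupa": 0.3151,
}

#: first inspection as a fraction of the mean stage duration
FIRST_CHECK_FRACTION = 0.6
EGG_FIRST_CHECK_FRACTION = 0.7
INSPECTION_INTERVAL_FRACTION = 0.1


def linear_truth(
    K: float,
    T_min: float,
    stage_fractions: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Per-stage share of the thermal constant for a linear ground truth.

    Returns the degree-day budget of each stage, ``K · fraction``; the
    mean duration of stage s at temperature T is then K_s/(T − T_min).
    """
    fr = dict(stage_fractions or DEFAULT_STAGE_FRACTIONS)
    total = sum(fr.values())
    return {s: K * fr[s] / total for s in STAGES}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth and protocol for one simulated rearing experiment.

    ``K`` and ``T_min`` define the linear truth for total development;
    ``stage_fractions`` splits it across stages.  ``mortality`` maps a
    stage (or a ``(stage, temperature)`` pair, which takes precedence) to
    the probability of dying at entry to that stage.  ``seed`` is
    mandatory: identical configs produce byte-identical cohorts.
    """

    K: float
    T_min: float
    temperatures: tuple[float, ...]
    n_per_temperature: int
    seed: int
    cv_duration: float = 0.10
    stage_fractions: Mapping[str, float] | None = None
    mortality: Mapping = field(default_factory=dict)
    first_check_fraction: float = FIRST_CHECK_FRACTION
    egg_first_check_fraction: float = EGG_FIRST_CHECK_FRACTION
    interval_fraction: float = INSPECTION_INTERVAL_FRACTION
    diet: str | None = None
    diet_duration_factor: float = 1.0

    def __post_init__(self):
        if self.cv_duration < 0:
            raise ValidationError("cv_duration must be >= 0")
        for frac in (self.first_check_fraction, self.egg_first_check_fraction):
            if not 0 < frac < 1:
                raise ValidationError("first-check fractions must lie in (0, 1)")
        if not 0 <= self.interval_fraction < 1:
            raise ValidationError("interval_fraction must lie in [0, 1)")
        for p in dict(self.mortality).values():
            if not 0 <= p <= 1:
                raise ValidationError("mortality probabilities must lie in [0, 1]")

    def stage_K(self) -> dict[str, float]:
        return linear_truth(self.K, self.T_min, self.stage_fractions)

    def stage_means(self, temperature: float) -> dict[str, float] | None:
        """True mean stage durations (days) at a temperature, or None when
        the model allows no development there."""
        if temperature <= self.T_min:
            return None
        kd = self.stage_K()
        return {
            s: self.diet_duration_factor * kd[s] / (temperature - self.T_min)
            for s in STAGES
        }

    def mortality_at(self, stage: str, temperature: float) -> float:
        m = dict(self.mortality)
        if (stage, temperature) in m:
            return float(m[(stage, temperature)])
        return float(m.get(stage, 0.0))


def observe_duration(
    true_duration: float,
    mean_duration: float,
    first_check_fraction: float,
    interval_fraction: float,
) -> float:
    """Duration as recorded under the midpoint inspection rule.

    Inspections fall at (first_check_fraction + j·interval_fraction) ×
    mean duration; the recorded time is the midpoint of the inspection
    that caught the landmark and the previous one (stage entry when the
    landmark predates the first check).  The recorded value deviates from
    the truth by at most half the inspection interval whenever the true
    duration exceeds the first-check time.
    """
    if interval_fraction == 0:
        return true_duration
    first = first_check_fraction * mean_duration
    interval = interval_fraction * mean_duration
    if true_duration <= first:
        return first / 2.0
    j = math.ceil((true_duration - first) / interval)
    return first + j * interval - interval / 2.0


def censoring_error_bound(
    config: SimulationConfig, temperature: float
) -> dict[str, float]:
    """Per-stage maximum censoring error (days): half the inspection interval.

    Valid whenever true stage durations exceed the first-check time,
    which holds for the moderate between-specimen CVs simulated here.
    """
    if config.interval_fraction <= 0:
        return {s: 0.0 for s in STAGES}
    means = config.stage_means(temperature)
    if means is None:
        raise ValidationError(f"no development at {temperature} °C")
    return {s: 0.5 * config.interval_fraction * means[s] for s in STAGES}


def landmark_error_bound(config: SimulationConfig, temperature: float) -> dict[str, float]:
    """Maximum censoring error of cumulative landmark times (days)."""
    from .dataset import LANDMARK_STAGES

    per_stage = censoring_error_bound(config, temperature)
    return {
        lm: sum(per_stage[s] for s in stages)
        for lm, stages in LANDMARK_STAGES.items()
    }


def simulate_cohort(config: SimulationConfig) -> list[DevelopmentRecord]:
    """Draw one cohort of specimen records under the configured truth.

    Per specimen and stage: death at stage entry with the configured
    probability truncates the record; otherwise the true duration is
    lognormal around the model mean with CV ``cv_duration`` and the
    observed duration follows the midpoint inspection rule.  Records
    carry their uncensored durations in ``true_durations``.
    """
    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.cv_duration**2))
    records: list[DevelopmentRecord] = []
    counter = 0
    for temp in config.temperatures:
        means = config.stage_means(temp)
        if means is None:
            warnings.warn(
                f"no development possible at {temp} °C (at or below the "
                f"threshold {config.T_min} °C); emitting all-censored records",
                stacklevel=2,
            )
            for _ in range(config.n_per_temperature):
                counter += 1
                records.append(
                    DevelopmentRecord(
                        specimen_id=f"sim{counter:05d}",
                        temperature=temp,
                        stage_durations={},
                        fate="died",
                        death_stage="egg",
                        diet=config.diet,
                        true_durations={},
                    ).validate()
                )
            continue
        for _ in range(config.n_per_temperature):
            counter += 1
            observed: dict[str, float] = {}
            truth: dict[str, float] = {}
            death_stage = None
            for stage in STAGES:
                if rng.random() < config.mortality_at(stage, temp):
                    death_stage = stage
                    break
                mean = means[stage]
                if config.cv_duration == 0:
                    d = mean
                else:
                    d = mean * math.exp(rng.normal(-0.5 * sigma**2, sigma))
                truth[stage] = d
                first = (
                    config.egg_first_check_fraction
                    if stage == "egg"
                    else config.first_check_fraction
                )
                observed[stage] = observe_duration(
                    d, mean, first, config.interval_fraction
                )
            records.append(
                DevelopmentRecord(
                    specimen_id=f"sim{counter:05d}",
                    temperature=temp,
                    stage_durations=observed,
                    fate="died" if death_stage else "emerged",
                    death_stage=death_stage,
                    diet=config.diet,
                    true_durations=truth,
                ).validate()
            )
    return records
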