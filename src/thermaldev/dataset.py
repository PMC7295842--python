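"""Data model and I/O for specimen-level development records.

The central objects are :class:`DevelopmentRecord` (one reared specimen:
constant rearing temperature, per-stage durations in days, fate),
:class:`LandmarkDataset` (per-temperature aggregates of time from
oviposition to a developmental landmark — the input every model-fitting
routine consumes) and :class:`MortalityTable` (stage-resolved death counts
per rearing group).

Bundled reference data
----------------------
The package ships the published per-temperature stage-duration means for
the Central European population of *Creophilus maxillosus* (ten constant
temperatures, 10–32.5 °C in 2.5 °C steps) together with size tables by
temperature and by diet.  Load them with :func:`load_stage_durations`,
:func:`load_sizes_by_temperature` and :func:`load_sizes_by_diet`; build
fitting inputs with :func:`cumulative_landmarks`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STAGES: tuple[str, ...] = ("egg", "L1", "L2", "L3", "pupa")

#: Developmental landmarks in chronological order, with the stages whose
#: durations sum to the time-to-landmark from oviposition.
LANDMARKS: tuple[str, ...] = (
    "hatching",
    "first_ecdysis",
    "second_ecdysis",
    "pupation",
    "eclosion",
)

LANDMARK_STAGES: dict[str, tuple[str, ...]] = {
    "hatching": ("egg",),
    "first_ecdysis": ("egg", "L1"),
    "second_ecdysis": ("egg", "L1", "L2"),
    "pupation": ("egg", "L1", "L2", "L3"),
    "eclosion": ("egg", "L1", "L2", "L3", "pupa"),
}

RECORD_COLUMNS = (
    "specimen_id",
    "temperature_C",
    "diet",
    "egg_d",
    "L1_d",
    "L2_d",
    "L3_d",
    "pupa_d",
    "fate",
    "death_stage",
)


class ValidationError(ValueError):
    """A record or dataset violates one of the documented invariants."""


@dataclass
class DevelopmentRecord:
    """One specimen's development history at constant temperature.

    ``stage_durations`` holds days spent in each completed stage; the keys
    present must form a prefix of ``STAGES`` (a larva cannot have a L3
    duration without a L2 duration).  ``fate`` is ``"emerged"`` iff all
    five stages are present, otherwise ``"died"`` with ``death_stage``
    naming the stage the specimen entered but did not complete.
    """

    specimen_id: str
    temperature: float
    stage_durations: dict[str, float] = field(default_factory=dict)
    fate: str = "died"
    death_stage: str | None = None
    diet: str | None = None
    #: true (pre-censoring) durations, populated by the simulator only
    true_durations: dict[str, float] | None = field(
        default=None, repr=False, compare=False
    )

    def validate(self) -> "DevelopmentRecord":
        present = [s for s in STAGES if s in self.stage_durations]
        extra = set(self.stage_durations) - set(STAGES)
        if extra:
            raise ValidationError(
                f"{self.specimen_id}: unknown stages {sorted(extra)}"
            )
        if present != list(STAGES[: len(present)]):
            raise ValidationError(
                f"{self.specimen_id}: stages {present} are not a prefix of {STAGES}"
            )
        for s in present:
            if not self.stage_durations[s] > 0:
                raise ValidationError(
                    f"{self.specimen_id}: non-positive duration for stage {s}"
                )
        if self.fate not in ("emerged", "died"):
            raise ValidationError(f"{self.specimen_id}: unknown fate {self.fate!r}")
        if (self.fate == "emerged") != (len(present) == len(STAGES)):
            raise ValidationError(
                f"{self.specimen_id}: fate {self.fate!r} inconsistent with "
                f"{len(present)}/{len(STAGES)} completed stages"
            )
        if self.fate == "died":
            if self.death_stage not in STAGES:
                raise ValidationError(
                    f"{self.specimen_id}: died record needs a death_stage in {STAGES}"
                )
            if self.death_stage in self.stage_durations:
                raise ValidationError(
                    f"{self.specimen_id}: death stage {self.death_stage} cannot "
                    "carry a completed duration"
                )
        return self

    def landmark_time(self, landmark: str) -> float | None:
        """Cumulative days from oviposition to *landmark*, None if not reached."""
        stages = LANDMARK_STAGES[landmark]
        if not all(s in self.stage_durations for s in stages):
            return None
        return float(sum(self.stage_durations[s] for s in stages))


@dataclass
class LandmarkDataset:
    """Per-temperature aggregate of time-to-landmark, the fitting input.

    ``rows`` has columns ``temperature_C`` (strictly increasing), ``D``
    (mean days from oviposition to the landmark), ``SE`` and ``N``.
    """

    landmark: str
    rows: pd.DataFrame

    def validate(self) -> "LandmarkDataset":
        if self.landmark not in LANDMARKS:
            raise ValidationError(f"unknown landmark {self.landmark!r}")
        r = self.rows
        missing = {"temperature_C", "D", "SE", "N"} - set(r.columns)
        if missing:
            raise ValidationError(f"LandmarkDataset missing columns {sorted(missing)}")
        t = r["temperature_C"].to_numpy(float)
        if len(t) and not np.all(np.diff(t) > 0):
            raise ValidationError("temperatures must be strictly increasing")
        if not np.all(r["D"].to_numpy(float) > 0):
            raise ValidationError("all D must be > 0")
        if not np.all(r["N"].to_numpy(float) >= 1):
            raise ValidationError("all N must be >= 1")
        return self

    @property
    def temperatures(self) -> np.ndarray:
        return self.rows["temperature_C"].to_numpy(float)

    @property
    def durations(self) -> np.ndarray:
        return self.rows["D"].to_numpy(float)

    @property
    def rates(self) -> np.ndarray:
        """Development rates 1/D (1/day)."""
        return 1.0 / self.durations

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class MortalityTable:
    """Stage-resolved death counts per rearing group (temperature or diet)."""

    groups: list[tuple[str, int, dict[str, int]]]

    def validate(self) -> "MortalityTable":
        for label, n, deaths in self.groups:
            if any(v < 0 or v != int(v) for v in deaths.values()):
                raise ValidationError(f"group {label}: negative/non-integer deaths")
            if sum(deaths.values()) > n:
                raise ValidationError(f"group {label}: more deaths than sampled")
        return self


# ---------------------------------------------------------------------------
# delimited-text I/O


def _parse_float(text: str, line_no: int, column: str) -> float:
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(
            f"line {line_no}: malformed number {text!r} in column {column}"
        ) from exc


def read_records(
    source, *, delimiter: str = ",", strict: bool = True
) -> tuple[list[DevelopmentRecord], list[str]]:
    """Read specimen records from delimited text.

    ``source`` may be a path or an open text handle.  Returns the validated
    records plus a list of per-row error messages (empty cells are treated
    as absent values).  With ``strict=True`` any error raises instead.
    """
    if hasattr(source, "read"):
        frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    else:
        frame = pd.read_csv(str(source), sep=delimiter, dtype=str, keep_default_na=False)
    missing = set(RECORD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValidationError(f"missing columns {sorted(missing)}")

    records: list[DevelopmentRecord] = []
    errors: list[str] = []
    for i, row in frame.iterrows():
        line_no = i + 2  # header is line 1
        try:
            durations = {}
            for s in STAGES:
                cell = row[f"{s}_d"].strip()
                if cell:
                    durations[s] = _parse_float(cell, line_no, f"{s}_d")
            rec = DevelopmentRecord(
                specimen_id=row["specimen_id"].strip(),
                temperature=_parse_float(row["temperature_C"], line_no, "temperature_C"),
                stage_durations=durations,
                fate=row["fate"].strip(),
                death_stage=row["death_stage"].strip() or None,
                diet=row["diet"].strip() or None,
            ).validate()
            records.append(rec)
        except ValidationError as exc:
            errors.append(f"line {line_no}: {exc}")
    if strict and errors:
        raise ValidationError("; ".join(errors))
    return records, errors


def write_records(records: Iterable[DevelopmentRecord], target, *, delimiter=",") -> None:
    """Write records in the same delimited schema ``read_records`` accepts."""
    rows = []
    for rec in records:
        row = {
            "specimen_id": rec.specimen_id,
            "temperature_C": rec.temperature,
            "diet": rec.diet or "",
            "fate": rec.fate,
            "death_stage": rec.death_stage or "",
        }
        for s in STAGES:
            row[f"{s}_d"] = rec.stage_durations.get(s, "")
        rows.append(row)
    frame = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    if hasattr(target, "write"):
        frame.to_csv(target, sep=delimiter, index=False)
    else:
        frame.to_csv(str(target), sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# bundled reference tables


def _load_csv(name: str) -> pd.DataFrame:
    with resources.files("thermaldev.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_stage_durations() -> pd.DataFrame:
    """Published stage-duration summary: temperature_C, stage, mean_d, se_d, n.

    ``stage`` runs over egg, L1, L2, L3, pupa plus ``total`` (oviposition to
    adult emergence, printed separately because per-stage Ns differ).
    Missing cells of the printed table are absent rows, never zeros.
    """
    return _load_csv("stage_durations.csv")


def load_sizes_by_temperature() -> pd.DataFrame:
    """Published length/weight summaries per rearing temperature (metadata)."""
    return _load_csv("sizes_by_temperature.csv")


def load_sizes_by_diet() -> pd.DataFrame:
    """Published length/weight summaries per diet at 24 °C (metadata)."""
    return _load_csv("sizes_by_diet.csv")


def cumulative_landmarks(
    stage_means: pd.DataFrame | None = None,
) -> dict[str, LandmarkDataset]:
    """Build per-landmark fitting datasets from a per-temperature stage table.

    ``stage_means`` follows the :func:`load_stage_durations` layout and
    defaults to the bundled table.  Time to a landmark at a temperature is
    the sum of the constituent stage means; a temperature lacking any
    constituent stage is excluded from that landmark.  Eclosion uses the
    printed ``total`` row where present (per-stage Ns differ, so the sum of
    stage means is not the mean total that was actually regressed).

    Aggregate SE is the quadrature sum of stage SEs and N the smallest
    constituent N — conservative summaries for display; fits are unweighted.
    """
    table = load_stage_durations() if stage_means is None else stage_means
    out: dict[str, LandmarkDataset] = {}
    for landmark, stages in LANDMARK_STAGES.items():
        rows = []
        for temp, grp in table.groupby("temperature_C"):
            by_stage = grp.set_index("stage")
            if landmark == "eclosion" and "total" in by_stage.index:
                m = by_stage.loc["total"]
                rows.append((float(temp), float(m["mean_d"]), float(m["se_d"]), int(m["n"])))
                continue
            if not all(s in by_stage.index for s in stages):
                continue
            sub = by_stage.loc[list(stages)]
            d = float(sub["mean_d"].sum())
            if not d > 0:
                raise ValidationError(
                    f"non-positive cumulative duration at {temp} °C for {landmark}"
                )
            se = float(np.sqrt((sub["se_d"] ** 2).sum()))
            rows.append((float(temp), d, se, int(sub["n"].min())))
        frame = pd.DataFrame(rows, columns=["temperature_C", "D", "SE", "N"])
        frame = frame.sort_values("temperature_C").reset_index(drop=True)
        out[landmark] = LandmarkDataset(landmark, frame).validate()
    return out


def landmark_dataset_from_records(
    records: Sequence[DevelopmentRecord], landmark: str
) -> LandmarkDataset:
    """Aggregate specimen records to per-temperature mean time-to-landmark."""
    rows = []
    for rec in records:
        t = rec.landmark_time(landmark)
        if t is not None:
            rows.append((rec.temperature, t))
    if not rows:
        raise ValidationError(f"no record reached landmark {landmark!r}")
    frame = pd.DataFrame(rows, columns=["temperature_C", "t"])
    agg = frame.groupby("temperature_C")["t"].agg(["mean", "sem", "count"]).reset_index()
    agg.columns = ["temperature_C", "D", "SE", "N"]
    agg["SE"] = agg["SE"].fillna(0.0)
    return LandmarkDataset(landmark, agg).validate()


# ---------------------------------------------------------------------------
# mortality statistics


def mortality_from_records(records: Sequence[DevelopmentRecord], by="temperature") -> MortalityTable:
    """Tabulate deaths by stage per temperature (or per diet)."""
    groups: dict[str, tuple[int, dict[str, int]]] = {}
    for rec in records:
        label = str(rec.temperature) if by == "temperature" else str(rec.diet)
        n, deaths = groups.setdefault(label, (0, {}))
        n += 1
        if rec.fate == "died":
            deaths[rec.death_stage] = deaths.get(rec.death_stage, 0) + 1
        groups[label] = (n, deaths)
    return MortalityTable(
        [(label, n, deaths) for label, (n, deaths) in groups.items()]
    ).validate()


def mortality_percentages(table: MortalityTable) -> dict[str, float]:
    """Percentage mortality per group: dead × 100 / sampled."""
    out = {}
    for label, n, deaths in table.groups:
        if n == 0:
            raise ValidationError(f"group {label}: zero specimens sampled")
        out[label] = 100.0 * sum(deaths.values()) / n
    return out


def mortality_chi_square(table: MortalityTable) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on groups × {dead, survived}.

    Returns (statistic, degrees of freedom, upper-tail p).
    """
    if len(table.groups) < 2:
        raise ValidationError("chi-square needs at least 2 groups")
    dead = np.array([sum(d.values()) for _, _, d in table.groups], float)
    total = np.array([n for _, n, _ in table.groups], float)
    if np.any(total == 0):
        raise ValidationError("every group needs n_sampled > 0")
    contingency = np.column_stack([dead, total - dead])
    res = stats.chi2_contingency(contingency, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
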