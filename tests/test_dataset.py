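"""Record I/O, landmark aggregation and mortality statistics."""

import io

import numpy as np
import pytest

import thermaldev as td
from thermaldev.dataset import (
    LANDMARK_STAGES,
    MortalityTable,
    ValidationError,
    cumulative_landmarks,
    load_stage_durations,
    mortality_chi_square,
    mortality_percentages,
    read_records,
    write_records,
)

CSV_HEADER = "specimen_id,temperature_C,diet,egg_d,L1_d,L2_d,L3_d,pupa_d,fate,death_stage"


def test_read_records_round_trip(record_factory):
    records = [
        record_factory("a", 25.0),
        record_factory("b", 20.0, died_at="L3"),
        record_factory("c", 17.5, diet="Calliphora_larvae"),
    ]
    buf = io.StringIO()
    write_records(records, buf)
    buf.seek(0)
    back, errors = read_records(buf)
    assert errors == []
    assert len(back) == 3
    for orig, rec in zip(records, back):
        assert rec.specimen_id == orig.specimen_id
        assert rec.temperature == orig.temperature
        assert rec.stage_durations == pytest.approx(orig.stage_durations)
        assert rec.fate == orig.fate
        assert rec.death_stage == orig.death_stage
        assert rec.diet == orig.diet


def test_read_records_rejects_stage_gap():
    # L3 duration present without an L2 duration violates the prefix rule
    row = "x1,25,,2.8,1.9,,13.8,,died,pupa"
    text = f"{CSV_HEADER}\n{row}\n"
    with pytest.raises(ValidationError, match="x1"):
        read_records(io.StringIO(text))
    _, errors = read_records(io.StringIO(text), strict=False)
    assert len(errors) == 1 and "line 2" in errors[0]


def test_read_records_reports_malformed_number():
    text = f"{CSV_HEADER}\nx1,25,,not_a_number,,,,,died,L1\n"
    _, errors = read_records(io.StringIO(text), strict=False)
    assert len(errors) == 1
    assert "line 2" in errors[0] and "egg_d" in errors[0]


def test_record_invariants(record_factory):
    with pytest.raises(ValidationError):
        td.DevelopmentRecord("z", 25.0, {"egg": -1.0}, fate="died", death_stage="L1").validate()
    with pytest.raises(ValidationError):  # emerged but incomplete
        td.DevelopmentRecord("z", 25.0, {"egg": 2.0}, fate="emerged").validate()
    rec = record_factory("ok", died_at="pupa")
    assert rec.landmark_time("pupation") == pytest.approx(2.8 + 1.9 + 2.3 + 13.8)
    assert rec.landmark_time("eclosion") is None


class TestCumulativeLandmarks:
    def test_fixture_shapes(self, landmarks):
        assert len(landmarks["hatching"]) == 10
        assert len(landmarks["first_ecdysis"]) == 10
        assert len(landmarks["second_ecdysis"]) == 10
        assert len(landmarks["pupation"]) == 8
        # eclosion completed only over 15-30 °C
        ecl = landmarks["eclosion"]
        assert len(ecl) == 7
        assert ecl.temperatures.min() == 15.0 and ecl.temperatures.max() == 30.0

    def test_second_ecdysis_sum_at_25(self, landmarks):
        row = landmarks["second_ecdysis"].rows.query("temperature_C == 25")
        assert row["D"].iloc[0] == pytest.approx(2.82 + 1.86 + 2.32)

    def test_eclosion_uses_printed_total(self, landmarks):
        # total development is taken from the printed total column, not a
        # sum of stage means computed over differing specimen subsets
        row = landmarks["eclosion"].rows.query("temperature_C == 30")
        assert row["D"].iloc[0] == pytest.approx(22.18)

    def test_monotone_across_landmarks(self, landmarks):
        order = list(LANDMARK_STAGES)
        for temp in landmarks["hatching"].temperatures:
            previous = 0.0
            for lm in order:
                rows = landmarks[lm].rows.query("temperature_C == @temp")
                if rows.empty:
                    continue
                d = rows["D"].iloc[0]
                assert d >= previous
                previous = d

    def test_all_zero_table_rejected(self):
        table = load_stage_durations().copy()
        table["mean_d"] = 0.0
        with pytest.raises(ValidationError):
            cumulative_landmarks(table)


class TestMortality:
    def test_percentages(self):
        table = MortalityTable(
            [
                ("32.5", 40, {"pupa": 40}),
                ("25", 40, {}),
                ("20", 40, {"egg": 3, "L3": 20}),
            ]
        ).validate()
        pct = mortality_percentages(table)
        assert pct["32.5"] == 100.0
        assert pct["25"] == 0.0
        assert pct["20"] == pytest.approx(57.5)

    def test_chi_square_matches_textbook_formula(self):
        # 2x2 oracle: chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))
        a, b = 10, 30  # dead / survived, group 1
        c, d = 30, 10
        table = MortalityTable([("g1", a + b, {"egg": a}), ("g2", c + d, {"egg": c})])
        stat, df, p = mortality_chi_square(table)
        n = a + b + c + d
        expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert stat == pytest.approx(expected)
        assert df == 1
        assert 0 < p < 1

    def test_chi_square_zero_for_identical_proportions(self):
        table = MortalityTable([("g1", 40, {"egg": 10}), ("g2", 80, {"egg": 20})])
        stat, _, p = mortality_chi_square(table)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_chi_square_invariant_to_group_order(self):
        groups = [("a", 40, {"egg": 5}), ("b", 40, {"L1": 12}), ("c", 35, {"pupa": 30})]
        s1, *_ = mortality_chi_square(MortalityTable(groups))
        s2, *_ = mortality_chi_square(MortalityTable(groups[::-1]))
        assert s1 == pytest.approx(s2)

    def test_degenerate_inputs(self):
        with pytest.raises(ValidationError):
            mortality_chi_square(MortalityTable([("only", 40, {"egg": 1})]))
        with pytest.raises(ValidationError):
            mortality_percentages(MortalityTable([("empty", 0, {})]))
        with pytest.raises(ValidationError):
            MortalityTable([("bad", 5, {"egg": 9})]).validate()
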