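"""Degree-day accumulation, age estimation, validation, isomorphen data."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermaldev as td
from thermaldev.dataset import ValidationError
from thermaldev.forensic import (
    TemperatureProfile,
    accumulate_ADD,
    estimate_age,
    isomorphen_data,
    validate,
)

ECLOSION = td.LinearFit("eclosion", 405.156, 0.0, 11.660, 0.0, 0.998, 7, (15, 30))


@st.composite
def step_profiles(draw):
    n = draw(st.integers(min_value=1, max_value=6))
    widths = draw(
        st.lists(st.floats(min_value=1.0, max_value=400.0), min_size=n, max_size=n)
    )
    temps = draw(
        st.lists(st.floats(min_value=0.0, max_value=35.0), min_size=n, max_size=n)
    )
    times = np.concatenate([[0.0], np.cumsum(widths)])
    return TemperatureProfile(times, np.asarray(temps + [temps[-1]]))


class TestAccumulate:
    def test_constant_profile_arithmetic(self):
        # 29.91 days at 25 °C above an 11.66 °C threshold
        profile = TemperatureProfile.constant(25.0, 29.91 * 24)
        add = accumulate_ADD(profile, 11.66)
        assert add == pytest.approx(29.91 * (25 - 11.66), rel=1e-12)
        assert add == pytest.approx(398.99, abs=0.01)

    def test_below_threshold_clips_to_zero(self):
        profile = TemperatureProfile.constant(8.0, 1000.0)
        assert accumulate_ADD(profile, 11.66) == 0.0

    def test_interval_refinement_invariance(self):
        coarse = TemperatureProfile(np.array([0.0, 48.0]), np.array([20.0, 20.0]))
        fine = TemperatureProfile(
            np.array([0.0, 7.0, 23.5, 48.0]), np.array([20.0, 20.0, 20.0, 20.0])
        )
        assert accumulate_ADD(coarse, 10.0) == pytest.approx(
            accumulate_ADD(fine, 10.0), rel=1e-12
        )

    def test_monotone_in_horizon(self):
        profile = TemperatureProfile(
            np.array([0.0, 24.0, 48.0, 96.0]), np.array([15.0, 5.0, 30.0, 30.0])
        )
        adds = [accumulate_ADD(profile, 10.0, h) for h in (0, 12, 24, 36, 60, 96)]
        assert all(b >= a for a, b in zip(adds, adds[1:]))

    def test_extrapolation_warns(self):
        profile = TemperatureProfile.constant(20.0, 24.0)
        with pytest.warns(UserWarning, match="beyond profile span"):
            add = accumulate_ADD(profile, 10.0, 48.0)
        assert add == pytest.approx(20.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValidationError):
            TemperatureProfile(np.array([]), np.array([]))


class TestEstimateAge:
    def test_constant_temperature_inverts_the_line(self):
        profile = TemperatureProfile.constant(25.0, 24 * 60)
        age_h = estimate_age(profile, ECLOSION)
        assert age_h / 24.0 == pytest.approx(405.156 / (25 - 11.660), rel=1e-9)
        assert age_h == pytest.approx(728.9, abs=0.1)

    def test_one_degree_day_per_day(self):
        fit = td.LinearFit("hatching", 1.0, 0.0, 10.0, 0.0, 1.0, 4, (10, 30))
        profile = TemperatureProfile.constant(11.0, 100.0)
        assert estimate_age(profile, fit) == pytest.approx(24.0, rel=1e-12)

    def test_insufficient_thermal_input(self):
        profile = TemperatureProfile.constant(15.0, 24.0)
        with pytest.raises(ValidationError, match="insufficient thermal input"):
            estimate_age(profile, ECLOSION)

    @settings(deadline=None, max_examples=100)
    @given(step_profiles(), st.floats(min_value=5.0, max_value=12.0))
    def test_round_trip_add_of_estimated_age_returns_K(self, profile, t_min):
        """estimate_age is the exact inverse of accumulate_ADD."""
        total = accumulate_ADD(profile, t_min)
        if total < 1.0:
            return
        K = 0.5 * total
        fit = td.LinearFit("eclosion", K, 0.0, t_min, 0.0, 1.0, 4, (15, 30))
        age_h = estimate_age(profile, fit)
        assert accumulate_ADD(profile, t_min, age_h) == pytest.approx(K, abs=1e-9)


class TestValidate:
    def test_relative_error_arithmetic(self, record_factory):
        d = (2.8, 1.9, 2.3, 13.8, 9.11)  # total 29.91 days
        rec = record_factory("v1", 25.0, durations=d)
        results, summary = validate([rec], ECLOSION, "eclosion")
        actual = 29.91 * (25 - 11.660)
        assert results[0].actual_ADD == pytest.approx(actual)
        assert results[0].relative_error == pytest.approx(
            abs(actual - 405.156) / actual
        )
        assert results[0].relative_error == pytest.approx(0.0155, abs=5e-4)
        assert summary.loc[0, "n"] == 1

    def test_zero_error_when_actual_equals_K(self, record_factory):
        D = 405.156 / (25 - 11.660)
        scale = D / 29.91
        rec = record_factory(
            "v2", 25.0, durations=tuple(scale * x for x in (2.8, 1.9, 2.3, 13.8, 9.11))
        )
        results, _ = validate([rec], ECLOSION, "eclosion")
        assert results[0].relative_error == pytest.approx(0.0, abs=1e-9)

    def test_records_missing_landmark_are_skipped(self, record_factory):
        recs = [record_factory("a", 25.0), record_factory("b", 25.0, died_at="L3")]
        results, _ = validate(recs, ECLOSION, "eclosion")
        assert [r.specimen_id for r in results] == ["a"]

    def test_simulated_truth_errors_within_censoring_effect(self):
        from thermaldev.synthetic import SimulationConfig, landmark_error_bound, simulate_cohort

        cfg = SimulationConfig(
            K=405.156, T_min=11.660, temperatures=(20.0, 25.0, 30.0),
            n_per_temperature=5, cv_duration=0.0, seed=3,
        )
        records = simulate_cohort(cfg)
        results, _ = validate(records, ECLOSION, "eclosion")
        for res in results:
            temp = float(res.group)
            bound = landmark_error_bound(cfg, temp)["eclosion"]
            assert res.relative_error <= bound * (temp - 11.660) / res.actual_ADD + 1e-9


class TestIsomorphen:
    def test_single_record_degenerate_quartiles(self, record_factory):
        table = isomorphen_data([record_factory("a", 25.0)])
        ecl = table.query("landmark == 'eclosion'")
        assert ecl["median_d"].iloc[0] == pytest.approx(2.8 + 1.9 + 2.3 + 13.8 + 9.6)
        assert ecl["q1_d"].iloc[0] == ecl["q3_d"].iloc[0]

    def test_median_of_odd_set(self, record_factory):
        recs = [
            record_factory(f"r{i}", 25.0, durations=(d, 1.0, 1.0, 1.0, 1.0))
            for i, d in enumerate((1.0, 2.0, 9.0))
        ]
        table = isomorphen_data(recs)
        hatch = table.query("landmark == 'hatching'")
        assert hatch["median_d"].iloc[0] == pytest.approx(2.0)
        # median-inclusive hinges on {1,2,9}: lower {1,2} -> 1.5, upper {2,9} -> 5.5
        assert hatch["q1_d"].iloc[0] == pytest.approx(1.5)
        assert hatch["q3_d"].iloc[0] == pytest.approx(5.5)

    def test_medians_monotone_across_landmarks(self, record_factory):
        rng = np.random.default_rng(0)
        recs = []
        for temp in (20.0, 25.0):
            for i in range(7):
                base = np.array([2.8, 1.9, 2.3, 13.8, 9.6]) * (25.0 / temp)
                noisy = base * rng.lognormal(0, 0.08, 5)
                recs.append(record_factory(f"{temp}-{i}", temp, durations=tuple(noisy)))
        table = isomorphen_data(recs)
        for temp, grp in table.groupby("temperature_C"):
            ordered = grp.set_index("landmark").loc[list(td.LANDMARKS)]
            assert ordered["median_d"].is_monotonic_increasing
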