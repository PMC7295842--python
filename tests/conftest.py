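import pytest

import thermaldev as td


@pytest.fixture(scope="session")
def landmarks():
    """Per-landmark fitting datasets built from the bundled duration table."""
    return td.cumulative_landmarks()


@pytest.fixture(scope="session")
def eclosion_fit(landmarks):
    return td.fit_thermal_summation(landmarks["eclosion"])


@pytest.fixture
def record_factory():
    """Build a valid emerged/died record with sensible defaults."""

    def make(
        specimen_id="s1",
        temperature=25.0,
        durations=(2.8, 1.9, 2.3, 13.8, 9.6),
        died_at=None,
        diet=None,
    ):
        stages = list(td.STAGES)
        if died_at is None:
            sd = dict(zip(stages, durations))
            return td.DevelopmentRecord(
                specimen_id, temperature, sd, fate="emerged", diet=diet
            ).validate()
        idx = stages.index(died_at)
        sd = dict(zip(stages[:idx], durations[:idx]))
        return td.DevelopmentRecord(
            specimen_id, temperature, sd, fate="died", death_stage=died_at, diet=diet
        ).validate()

    return make
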