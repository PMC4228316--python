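import pytest

import tailorkit as tk


@pytest.fixture(scope="session")
def catalog() -> tk.VariableCatalog:
    return tk.default_catalog()


@pytest.fixture(scope="session")
def library() -> tk.MessageLibrary:
    return tk.default_library()


@pytest.fixture(scope="session")
def schedule() -> tk.WaveSchedule:
    return tk.default_schedule()


@pytest.fixture(scope="session")
def feedback_chain(catalog) -> tk.RuleChain:
    """The 12-clause activity feedback chain (guideline x disability x
    post-diagnosis change), default code 13."""
    return catalog.feedback_def("aerobic_feedback").chain


@pytest.fixture()
def full_record() -> tk.ParticipantRecord:
    """A fully-answered baseline record of a moderately active participant."""
    return tk.ParticipantRecord(
        participant_id="FIX01",
        bindings={"baseline": {
            "first_name": "Jane",
            "strenuous_sessions": 0, "strenuous_minutes": 0,
            "moderate_sessions": 5, "moderate_minutes": 30,
            "resistance_exercises": 2,
            "disability": 2, "aerobic_change": 1,
            "age": 56.0, "bmi": 26.6, "married": 1,
        }},
    )


@pytest.fixture()
def empty_record() -> tk.ParticipantRecord:
    return tk.ParticipantRecord(participant_id="FIX02", bindings={"baseline": {}})


@pytest.fixture(scope="session")
def small_cohort() -> list[tk.ParticipantRecord]:
    return tk.simulate_baseline(tk.default_cohort_config(), n=10, seed=11)
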