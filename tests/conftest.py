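import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def coded_cohort():
    """A default synthetic cohort, coded and scenario-reassigned."""
    from pumppass import coding, synth

    records, truth = synth.gen_fish_cohort(
        synth.CohortScenario(seed=11, lingering_prob=0.15)
    )
    coded = coding.code_records(coding.reassign_scenarios(records))
    coded, _ = coding.remove_length_outliers(coded)
    return coded, truth


@pytest.fixture(scope="session")
def pump_trace():
    """One default pump-passage trace with its ground-truth marks."""
    from pumppass import synth

    return synth.gen_pressure_trace(synth.TraceScenario(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
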