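import pytest

from trialoptim import SyntheticCohortConfig, generate_cohort, table4_cohort


@pytest.fixture(scope="session")
def table4():
    """The 17 modified trials lifted from the packaged modification table."""
    return table4_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A small synthetic cohort with some missing results, plus its truth table."""
    cfg = SyntheticCohortConfig(n_trials=40, seed=11, missing_result_prob=0.15)
    return generate_cohort(cfg)
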