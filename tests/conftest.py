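import pytest

from postpipe.config import ScoringConfig
from postpipe.score import score_cohort
from postpipe.synthdata import make_fixture_cohort


@pytest.fixture(scope="session")
def default_config():
    return ScoringConfig()


@pytest.fixture(scope="session")
def fixture_cohort():
    return make_fixture_cohort()


@pytest.fixture(scope="session")
def scored_fixture(fixture_cohort, default_config):
    breakdowns, outcomes = score_cohort(fixture_cohort, default_config)
    return breakdowns, outcomes
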