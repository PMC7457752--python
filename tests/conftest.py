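import pytest
from hypothesis import HealthCheck, settings

from oncovalue import EsmoRuleTable, load_fixtures, score_fixture_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=100,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rules():
    return EsmoRuleTable.default()


@pytest.fixture(scope="session")
def initial_fixtures():
    return load_fixtures("initial")


@pytest.fixture(scope="session")
def updated_fixtures():
    return load_fixtures("updated")


@pytest.fixture(scope="session")
def scored_initial(initial_fixtures, rules):
    return score_fixture_cohort(initial_fixtures, rules=rules)


@pytest.fixture(scope="session")
def scored_updated(updated_fixtures, rules):
    return score_fixture_cohort(updated_fixtures, rules=rules)
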