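import pytest

from chw_incentives import Catchment, fixtures


@pytest.fixture(scope="session")
def catalog():
    return fixtures.fixture_catalog()


@pytest.fixture(scope="session")
def by_id(catalog):
    return {d.id: d for d in catalog}


@pytest.fixture(scope="session")
def demo():
    return fixtures.fixture_demographic_rates()


@pytest.fixture(scope="session")
def rates():
    return fixtures.fixture_rates()


@pytest.fixture(scope="session")
def observed():
    return fixtures.fixture_observed_payments()


@pytest.fixture(scope="session")
def scenario_totals():
    return fixtures.fixture_scenario_totals()


@pytest.fixture(scope="session")
def series_dists():
    return fixtures.fixture_series_distributions()


@pytest.fixture
def catchment():
    return Catchment(1000)
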