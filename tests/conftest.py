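import pytest

from ohca_cea import (
    CohortConfig,
    default_specs,
    point_estimates,
    synthesize_life_table,
)


@pytest.fixture(scope="session")
def specs():
    return default_specs()


@pytest.fixture(scope="session")
def means(specs):
    """Every parameter at its point estimate."""
    return point_estimates(specs)


@pytest.fixture(scope="session")
def table():
    return synthesize_life_table()


@pytest.fixture(scope="session")
def config():
    return CohortConfig()
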