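import pytest

from cdburden.costs import load_unit_costs
from cdburden.scoring import load_norms, load_value_set
from cdburden.synth import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def unit_costs():
    return load_unit_costs()


@pytest.fixture(scope="session")
def value_set():
    return load_value_set()


@pytest.fixture(scope="session")
def norms():
    return load_norms()


@pytest.fixture(scope="session")
def cohort200():
    return generate_cohort(GeneratorConfig(n=200, seed=42))


@pytest.fixture(scope="session")
def cohort_large():
    return generate_cohort(GeneratorConfig(n=10_000, seed=7))
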