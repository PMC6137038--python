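import pytest

from turtledose import GeneratorParams, generate_necropsy_cohort


@pytest.fixture(scope="session")
def default_params() -> GeneratorParams:
    return GeneratorParams(seed=20260921)


@pytest.fixture(scope="session")
def cohort(default_params):
    """One default 246-animal cohort, shared across tests."""
    return generate_necropsy_cohort(default_params)


@pytest.fixture(scope="session")
def big_cohort(default_params):
    """A 10,000-animal cohort for marginal-fidelity checks."""
    return generate_necropsy_cohort(
        default_params.with_(n_animals=10_000, seed=99))
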