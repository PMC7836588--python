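import numpy as np
import pytest

from arfcea import (
    DistributionSpec,
    ParameterSet,
    builtin_acute_parameters,
    builtin_nma_parameters,
    mean_draw,
    run_psa,
)

ACCEPTANCE_SEED = 1
ACCEPTANCE_ITERATIONS = 100_000


@pytest.fixture(scope="session")
def acute_params():
    return builtin_acute_parameters()


@pytest.fixture(scope="session")
def nma_params():
    return builtin_nma_parameters(n_samples=10_000, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def base_psa(acute_params):
    """Large base-case PSA shared by acceptance and property tests."""
    return run_psa(acute_params, n_iterations=ACCEPTANCE_ITERATIONS, seed=ACCEPTANCE_SEED)


@pytest.fixture(scope="session")
def nma_psa(nma_params):
    return run_psa(nma_params, n_iterations=ACCEPTANCE_ITERATIONS, seed=ACCEPTANCE_SEED)


def degenerate_parameter_set(template: ParameterSet | None = None) -> ParameterSet:
    """All-point-mass version of a parameter set (each at its mean)."""
    if template is None:
        template = builtin_acute_parameters()
    means = mean_draw(template).as_dict()
    specs = {}
    for name, value in means.items():
        if name in ("p_death0", "p_int0", "utility"):
            specs[name] = DistributionSpec(name, "empirical", (value,))
        else:
            specs[name] = DistributionSpec(name, "normal", (value, 0.0))
    return ParameterSet(**specs, scenario_name="degenerate")


@pytest.fixture
def degenerate_params():
    return degenerate_parameter_set()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
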