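import numpy as np
import pytest

from cavte_cea import base_case_parameters
from cavte_cea.cea import evaluate_strategies
from cavte_cea.sensitivity import run_psa


@pytest.fixture(scope="session")
def params():
    return base_case_parameters()


@pytest.fixture(scope="session")
def results_5y(params):
    """Deterministic 5-year cohort results for the three main strategies."""
    return evaluate_strategies(params, ["placebo", "doacs", "lmwhs"], 60)


@pytest.fixture(scope="session")
def psa_small(params):
    """A small seeded PSA shared by the stochastic-property tests."""
    return run_psa(params, 200, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
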