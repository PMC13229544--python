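import numpy as np
import pytest

from doseresp import synthetic as syn
from doseresp.nuisance import LearnerConfig


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def fast_learner():
    return LearnerConfig(learner="ridge_poly")


@pytest.fixture(scope="session")
def sample_cubic_small():
    return syn.generate_dataset(syn.DgpSpec("cubic_alt", 300, 11))


@pytest.fixture(scope="session")
def sample_flat_small():
    return syn.generate_dataset(syn.DgpSpec("flat_null", 300, 12))


@pytest.fixture(scope="session")
def sample_cubic_large():
    return syn.generate_dataset(syn.DgpSpec("cubic_alt", 2000, 13))


@pytest.fixture(scope="session")
def oracle_q_cubic():
    return syn.OracleOutcomeRegression("cubic_alt")


@pytest.fixture(scope="session")
def oracle_q_flat():
    return syn.OracleOutcomeRegression("flat_null")


@pytest.fixture(scope="session")
def oracle_g():
    return syn.OracleConditionalDensity()
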