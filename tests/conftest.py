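import numpy as np
import pytest

from psmcea import SurvivalDistribution
from psmcea.config import load_config
from psmcea.ipd import PseudoIPD


@pytest.fixture(scope="session")
def base_config() -> dict:
    return load_config()


@pytest.fixture(scope="session")
def loglogistic_pfs() -> SurvivalDistribution:
    # camrelizumab PFS base case
    return SurvivalDistribution("loglogistic", 2.0011, 0.1471)


@pytest.fixture(scope="session")
def loglogistic_os() -> SurvivalDistribution:
    # camrelizumab OS base case
    return SurvivalDistribution("loglogistic", 1.2879, 0.04461)


@pytest.fixture(scope="session")
def uncensored_loglogistic_ipd() -> PseudoIPD:
    """500 uncensored draws from loglogistic(shape=2.0, scale=0.15), fixed seed."""
    rng = np.random.default_rng(20240515)
    t = SurvivalDistribution("loglogistic", 2.0, 0.15).rvs(500, rng)
    return PseudoIPD(t, np.ones_like(t))
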