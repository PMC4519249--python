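import numpy as np
import pytest
from hypothesis import settings

from convtx import RNAKinetics, RateTable, TIConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def study_ti():
    return TIConfig.study_defaults(n_rounds=3000, seed=7)


@pytest.fixture()
def kin():
    return RNAKinetics()


@pytest.fixture()
def simple_rates():
    """A fixed, hand-checkable rate table (nM/s)."""
    return RateTable.from_rates(0.05, 0.04, 0.01, 0.008)
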