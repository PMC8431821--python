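import numpy as np
import pytest

from stridelearn.models import ABParams, ModABParams, ModSUParams, SUParams
from stridelearn.schedules import make_schedule


@pytest.fixture(scope="session")
def su_params():
    return SUParams(A=0.99, C=0.46, F=5.0e-4, E=0.95)


@pytest.fixture(scope="session")
def ab_params():
    return ABParams(beta=0.22, sigma2_lik=63.9)


@pytest.fixture(scope="session")
def mod_su_params():
    return ModSUParams(A=0.99, C=0.46, F=2.9e-3, E=0.99, gamma_LV=0.76, gamma_HV=0.53)


@pytest.fixture(scope="session")
def mod_ab_params():
    return ModABParams(beta_vf=0.20, sigma2_vf=78.86, beta_novf=1.0e-3, sigma2_novf=2.05)


@pytest.fixture(scope="session")
def constant_schedule():
    return make_schedule("constant", seed=0)


@pytest.fixture(scope="session")
def schedules_by_condition():
    return {c: make_schedule(c, seed=7) for c in ("constant", "LV", "HV")}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
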