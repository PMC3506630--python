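import math

import numpy as np
import pytest

from prefnet import FearFactor, FlexibilityProfile, KernelRng, grow_network


@pytest.fixture(scope="session")
def small_network():
    """A relaxed beta=inf preferred-degree network reused across tests."""
    rng = KernelRng(42, stream=1)
    return grow_network(300, FlexibilityProfile(kappa=10.5, beta=math.inf), rng, burn_in_mcs=400)


@pytest.fixture()
def rigid_profile():
    return FlexibilityProfile(kappa=10.5, beta=math.inf)


@pytest.fixture()
def typical_fear():
    return FearFactor(kind="typical", kappa0=20.5, kappa_inf=12.5, x_c=0.4)


@pytest.fixture()
def rng():
    return KernelRng(7, stream=1)


@pytest.fixture()
def np_rng():
    return np.random.default_rng(7)
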