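import numpy as np
import pytest

from axonradius.signal_models import TissueParams, gradient_for_bvalue
from axonradius.synth import paper_protocol

D0_DEFAULT = 2.5


@pytest.fixture(scope="session")
def grad_b6():
    return gradient_for_bvalue(6.0, 15.0, 30.0)


@pytest.fixture(scope="session")
def grad_b30():
    return gradient_for_bvalue(30.0, 15.0, 30.0)


@pytest.fixture(scope="session")
def shell_pair(grad_b6, grad_b30):
    return (grad_b6, grad_b30)


@pytest.fixture(scope="session")
def protocol():
    return paper_protocol()


@pytest.fixture()
def tissue():
    return TissueParams(f=0.6, Dpar=2.2, p2=0.7, D0=D0_DEFAULT, r=3.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
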