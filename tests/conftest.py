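import numpy as np
import pytest

import runtumble as rt
from runtumble import reference


@pytest.fixture(scope="session")
def r1_hom():
    return reference.r1_homogeneous()


@pytest.fixture(scope="session")
def r1_het():
    return reference.r1_heterogeneous()


@pytest.fixture(scope="session")
def flat_response():
    """Concentration-independent response with tumbling bias 0.2."""
    return rt.HomogeneousResponse(tb0=0.2, tb_inf=0.2, k_r=1.0, h_r=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
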