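import numpy as np
import pytest

from invadosim import network as nw
from invadosim import synthetic as syn


@pytest.fixture(scope="session")
def control_trace() -> syn.FrapTrace:
    """Noiseless control recovery on the default 0-330 s grid."""
    return syn.generate_control_trace()


@pytest.fixture(scope="session")
def baf_trace() -> syn.FrapTrace:
    """Noiseless bafilomycin (single-exponential) recovery."""
    return syn.generate_bafilomycin_trace()


@pytest.fixture(scope="session")
def default_network() -> nw.ReactionNetwork:
    """Calibrated-default network, dimer cap (max_m14 = 2)."""
    return nw.build_network()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
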