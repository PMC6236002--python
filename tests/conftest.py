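import numpy as np
import pytest

from spikescape import LFPParams, NetworkParams


@pytest.fixture
def net():
    return NetworkParams()


@pytest.fixture
def lfp_params():
    return LFPParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_net():
    """A miniature network that simulates in well under a second."""
    p = NetworkParams(
        T_sim=100.0, T_trans=20.0, T_STIM=49.0, t_STIM=10.0,
        N_EX=40, N_IN=10, N_STIM=5,
        L=1.0, R_STIM=0.2, R=0.3, K_STIM=3,
        dl_bin=0.25,
    )
    p.validate()
    return p
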