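import numpy as np
import pytest

from oscent.models import ForcingProgram, KimForgerParams
from oscent.simulate import SimConfig, euler_maruyama


@pytest.fixture(scope="session")
def kf_params():
    return KimForgerParams()


@pytest.fixture(scope="session")
def quiet_forcing():
    """No input: free-running conditions."""
    return ForcingProgram(T=1.0, Imax=0.0)


@pytest.fixture(scope="session")
def kf_free_run(kf_params, quiet_forcing):
    """Deterministic free-running Kim-Forger trajectory (50 time units)."""
    cfg = SimConfig(t_end=50.0, seed=0)
    return euler_maruyama(kf_params, quiet_forcing, cfg)
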