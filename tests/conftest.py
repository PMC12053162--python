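import numpy as np
import pytest

from microrelax import EchoSchedule, RelaxationParams


@pytest.fixture
def sched16():
    """The acquisition default: 16 echoes from 1.25 ms, 1.2 ms apart."""
    return EchoSchedule.default()


@pytest.fixture
def sched48():
    """Three concatenated repetitions of the default schedule."""
    return EchoSchedule.default(n_repetitions=3)


@pytest.fixture
def sn_params():
    """Substantia-nigra-like median decay parameters."""
    return RelaxationParams(S0=500.0, R2_micro=23.0, Omega2=0.85e4,
                            R2_nano=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
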