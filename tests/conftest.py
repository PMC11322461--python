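import numpy as np
import pytest

from circasleep import CohortConfig, EffectSpec, Hypnogram
from circasleep.io import STATES


@pytest.fixture
def rng():
    return np.random.default_rng(20240731)


@pytest.fixture
def small_config():
    """Compact cohort config for fast tests (24 h at 100 Hz)."""
    return CohortConfig(n_per_group=1, duration_h=24.0, fs=100.0, seed=11)


@pytest.fixture
def effects():
    return EffectSpec()


def random_hypnogram(rng, n_min=10, n_max=400, epoch_s=10.0):
    """Arbitrary state sequence with a random ZT anchor (not chain-derived)."""
    n = int(rng.integers(n_min, n_max + 1))
    states = rng.choice(list(STATES), size=n)
    start_zt = float(rng.uniform(0, 24))
    return Hypnogram(states=states, epoch_s=epoch_s, start_zt=start_zt)


@pytest.fixture
def make_hypnogram():
    def _make(states, epoch_s=10.0, start_zt=0.0):
        return Hypnogram(states=np.array(list(states)), epoch_s=epoch_s,
                         start_zt=start_zt)
    return _make
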