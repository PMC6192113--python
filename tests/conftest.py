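import numpy as np
import pytest

from segtrend import TimeVector, TrendConfig


@pytest.fixture
def times20() -> TimeVector:
    return TimeVector(np.arange(1.0, 21.0))


@pytest.fixture
def hinge_gene(times20):
    """Noiseless up-then-flat gene: slope 1 until t=10, flat after."""
    y = np.where(times20.values <= 10.0, times20.values, 10.0)
    return y


@pytest.fixture
def replicated_times() -> TimeVector:
    """8 distinct time points, 3 replicates each, plus one extra at t=1 (N=25)."""
    t = np.sort(np.concatenate([np.repeat(np.arange(1.0, 9.0), 3), [1.0]]))
    return TimeVector(t)


@pytest.fixture
def default_config() -> TrendConfig:
    return TrendConfig(seed=0)
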