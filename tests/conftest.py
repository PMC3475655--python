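import numpy as np
import pytest

from vasoburst import load_params, simulate


@pytest.fixture(scope="session")
def m1():
    return load_params("m1")


@pytest.fixture(scope="session")
def m1_train_long(m1):
    """A long phasic run shared across analysis tests (enough bursts and
    ISIs for stable histogram/hazard statistics)."""
    return simulate(m1, 2_000_000, seed=123).train


def poisson_train(rate_hz, duration_ms, rng):
    """Homogeneous Poisson spike train (oracle input for analysis tests)."""
    n = rng.poisson(rate_hz * duration_ms / 1000.0)
    times = np.sort(rng.uniform(0, duration_ms, n))
    # enforce strict increase for the SpikeTrain contract
    times = np.unique(times)
    from vasoburst import SpikeTrain
    return SpikeTrain(times, float(duration_ms))
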