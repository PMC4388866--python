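import numpy as np
import pytest

from dispvar import CountMatrix, SimulationSpec, simulate_two_group


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_two_group():
    """A modest simulated two-group experiment with known truth."""
    cm, truth = simulate_two_group(SimulationSpec(
        m=300, group_sizes=(5, 5), pi1=0.2, fc_scheme=1.5, sigma=0.5,
        seed=77))
    return cm, truth


@pytest.fixture
def toy_cm():
    counts = np.array([[12, 9, 20, 25],
                       [0, 1, 0, 2],
                       [100, 110, 95, 120]])
    return CountMatrix(counts=counts, group=[1, 1, 2, 2],
                       lib_size=[1e6, 1e6, 1e6, 1e6])
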