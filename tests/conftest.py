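import warnings

import numpy as np
import pytest

from phagedefense.params import EcologyParams, StrategyParams

# the reference habitats intentionally sit outside some surveyed parameter
# ranges; the advisory warnings are not under test
warnings.filterwarnings("ignore", message=".*outside the surveyed range.*")


@pytest.fixture(autouse=True)
def _silence_range_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*outside the surveyed range.*")
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_eco():
    """A minimal grid (P0=3, Q=4) with moderate rates for exact checks."""
    return EcologyParams(A=2.0, B=0.1, C=1e-3, E=0.05, F=0.5, G=1.0,
                         T=0.8, psi0=50.0, Q=4, P0=3)


@pytest.fixture
def fig5_reduced():
    """The reference habitat at reduced intracellular resolution (Q=200)."""
    return EcologyParams(A=28.0, B=0.05, C=1e-8, E=0.0125, F=4.0, G=1.0,
                         T=1.0, psi0=1e8, Q=200)


@pytest.fixture
def caption_strategy():
    return StrategyParams(a=0.98716, r=0.00584)


def random_small_state(rng, eco, scale=10.0):
    n = rng.random((eco.P0, eco.Q + 1)) * scale
    # leave some states empty to exercise sparsity handling
    n[rng.random(n.shape) < 0.3] = 0.0
    return n
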