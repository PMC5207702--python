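import numpy as np
import pytest

from cellfrust.dinbs import DinBsSpec, MaxFrustSpec, build_max_frustrated_ilists
from cellfrust.engine import Population


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_pop(rng):
    """Random 8-cell-per-type population, full connectivity."""
    return Population.random(8, rng)


@pytest.fixture
def dinbs96():
    return DinBsSpec(n=96, n_rare=2)


@pytest.fixture
def maxfrust96(dinbs96):
    return build_max_frustrated_ilists(MaxFrustSpec(n_top=24, seed=7), dinbs96)
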