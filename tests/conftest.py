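import numpy as np
import pytest

from bordertrap import OrchardScenario


@pytest.fixture
def rng():
    return np.random.default_rng(20230517)


@pytest.fixture
def scenario():
    """Default synthetic trial scenario (four-plot border layout)."""
    return OrchardScenario(seed=7)


@pytest.fixture
def small_scenario():
    """Reduced trial for fast end-to-end tests."""
    return OrchardScenario(n_points=48, seed=7)
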