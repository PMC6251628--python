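import numpy as np
import pytest

from methylhet.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_config():
    """A cheap configuration for structural (non-statistical) checks."""
    return SimulationConfig(seed=7, n_regions=50, cpgs_per_region=5)
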