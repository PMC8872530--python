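import numpy as np
import pytest

from hairdna import simulate


@pytest.fixture(scope="session")
def small_panel():
    """A 500-site panel with uniform(0.05, 0.95) frequencies."""
    return simulate.simulate_panel(500, seed=11)


@pytest.fixture(scope="session")
def mt_reference():
    """A synthetic 2,000 bp circular mtDNA-like reference."""
    return simulate.random_mt_reference(2000, seed=12)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
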