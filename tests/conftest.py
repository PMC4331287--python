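import numpy as np
import pytest

from crocallometry.simulate import simulate_crocodilian_panel


@pytest.fixture
def default_panel():
    """One default synthetic panel pair with a fixed seed."""
    return simulate_crocodilian_panel(seed=42)


@pytest.fixture
def noisy_pairs():
    """A moderately noisy power-law sample with known generating truth."""
    rng = np.random.default_rng(7)
    log_x = rng.uniform(1.0, 3.0, size=60)
    log_y = -5.1240 + 2.9221 * log_x + rng.normal(0, 0.05, size=60)
    return np.column_stack([10.0**log_x, 10.0**log_y])
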