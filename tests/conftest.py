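import numpy as np
import pytest


@pytest.fixture(scope="session")
def week_grid():
    """Inclusive 0.1-week grid over the full 0-42 week domain."""
    return np.round(np.arange(0.0, 42.0 + 1e-9, 0.1), 10)


@pytest.fixture(scope="session")
def pregnancy_grid(week_grid):
    """The 0-40 week portion used for 'during pregnancy' extrema."""
    return week_grid[week_grid <= 40.0 + 1e-12]
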