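import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the _oracles helper

from ecoeff.synthetic import SyntheticConfig, generate_regression_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default 30x10 baseline-DGP panel (linear NDI effect only)."""
    return generate_regression_panel(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def noise_free_panel():
    return generate_regression_panel(SyntheticConfig(seed=1, sigma_eps=0.0))
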