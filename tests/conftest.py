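import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gibeta import default_params, steady_state_full, topp_human_params


@pytest.fixture(scope="session")
def params():
    """Default wildtype-female parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def beta_ref(params):
    """Reference β-cell mass: full-model steady state of the defaults."""
    return steady_state_full(params)[2]


@pytest.fixture(scope="session")
def human_params():
    """Converted classical human Topp parameter set (no feedback)."""
    return topp_human_params()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
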