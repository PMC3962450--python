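import sys
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from dtiretest import default_phantom_config, default_scheme, generate_cohort

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def scheme42():
    """The study's acquisition scheme: 7 b=0 plus 42 directions at b=1000."""
    return default_scheme(42, 7, 1000.0)


@pytest.fixture(scope="session")
def small_scheme():
    """Minimal identifiable scheme for cheap tests."""
    return default_scheme(12, 2, 1000.0)


@pytest.fixture(scope="session")
def tiny_cohort(scheme42):
    """3 controls + 2 patients on the default grid, with noise."""
    cfg = default_phantom_config(n_control=3, n_hd=2, seed=7)
    return generate_cohort(cfg, scheme42)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
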