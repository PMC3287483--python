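import numpy as np
import pytest

from sitepin.config import RunConfig
from sitepin.tagmodel import build_profile


@pytest.fixture(scope="session")
def model120():
    """Template for the canonical simulation conditions (L=120, alpha=10, D=300)."""
    return build_profile(120.0, 10.0, 300)


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
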