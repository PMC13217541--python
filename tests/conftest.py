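import numpy as np
import pytest

from abfekit import fixtures
from abfekit.gbsa import GBConfig


@pytest.fixture(scope="session")
def toy_complex():
    """Clean pocket fixture shared by read-only tests."""
    return fixtures.make_toy_complex(fixtures.FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def vacuum_gb():
    """GB configuration with eps_in = 1 (the printed-formula limit)."""
    return GBConfig(eps_in=1.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
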