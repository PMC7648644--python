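import numpy as np
import pytest

from habrange import WorldConfig, analytic_fixture, gen_world


@pytest.fixture(scope="session")
def fixture_world():
    """The exactly solvable 4x4 world and its expected-value ledger."""
    return analytic_fixture()


@pytest.fixture(scope="session")
def hist_world():
    """A default synthetic world, historical period only."""
    return gen_world(WorldConfig(seed=7), future=False)


@pytest.fixture(scope="session")
def future_world():
    """A synthetic world with two emission and two socio-economic pathways."""
    cfg = WorldConfig(seed=7, rcps=("2.6", "6.0"), ssps=("1", "3"))
    return gen_world(cfg, future=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
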