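import numpy as np
import pytest

from soildiv import simulate as sim
from soildiv import diversity as dv


@pytest.fixture(scope="session")
def design():
    return sim.PlotDesign()


@pytest.fixture(scope="session")
def coords(design):
    return design.coordinates()[["x", "y"]].to_numpy()


@pytest.fixture(scope="session")
def default_table():
    """One default synthetic survey (400 quadrats), shared across tests."""
    return sim.simulate_quadrat_table(seed=1)


@pytest.fixture(scope="session")
def default_diversity(default_table):
    return dv.diversity_indices(default_table)


@pytest.fixture()
def rng():
    # fresh, identically seeded generator per test: order-independent
    return np.random.default_rng(20240915)
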