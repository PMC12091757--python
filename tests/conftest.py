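import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import nanocap as nc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ff():
    return nc.default_forcefield()


@pytest.fixture(scope="session")
def hexagon(ff):
    return nc.make_fixture("hexagon_ring", element="C", length=1.42, forcefield=ff)


@pytest.fixture(scope="session")
def single_atom(ff):
    return nc.make_fixture("single_atom", element="C", forcefield=ff)


@pytest.fixture(scope="session")
def fluorouracil(ff):
    return nc.drug_molecule("FU", forcefield=ff)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
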