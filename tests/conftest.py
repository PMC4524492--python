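import numpy as np
import pytest

from plastarch import simulate as sim


@pytest.fixture(scope="session")
def default_cfg():
    return sim.SimConfig(seed=42)


@pytest.fixture(scope="session")
def ancestor(default_cfg):
    return sim.make_ancestor(default_cfg)


@pytest.fixture(scope="session")
def ancestor_realized(ancestor):
    return sim.realize(ancestor, taxon="ancestor")


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
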