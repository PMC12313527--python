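import numpy as np
import pytest

from cgforge.priors import PriorModel
from cgforge.synthetic import chain_spec, generate_toy_frameset, toy_topologies
from cgforge.framesets import map_frameset


@pytest.fixture(scope="session")
def toy_spec():
    return chain_spec(n_beads=6, seed=11)


@pytest.fixture(scope="session")
def toy_frameset(toy_spec):
    return generate_toy_frameset(toy_spec, 600)


@pytest.fixture(scope="session")
def toy_tops(toy_spec):
    return toy_topologies(toy_spec)


@pytest.fixture(scope="session")
def toy_cg(toy_frameset, toy_tops):
    _, ctop = toy_tops
    return map_frameset(toy_frameset, ctop)


@pytest.fixture
def simple_prior():
    """Hand-set prior covering every term class via pooled fallbacks."""
    return PriorModel(
        bond_terms={None: (0.38, 800.0)},
        angle_terms={None: (2.0, 30.0)},
        dihedral_terms={None: [(1.5, 1, 0.3), (0.8, 2, -0.5), (0.3, 3, 1.0)]},
        repulsion_terms={None: (0.4, 3.0, 6.0)},
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
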