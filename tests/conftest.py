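import itertools

import numpy as np
import pytest

from bindscan.energetics import EnergyMatrix
from bindscan.fixtures import (
    FixtureRecipe,
    make_toy_complex,
    make_toy_gene,
    make_uniform_catalog,
)
from bindscan.mutprob import CancerWeights
from bindscan.structures import read_structure


@pytest.fixture(scope="session")
def toy_recipe():
    return FixtureRecipe(n_residues_per_partner=3, interface_gap=4.0, seed=1)


@pytest.fixture(scope="session")
def toy_pdb(toy_recipe):
    return make_toy_complex(toy_recipe)


@pytest.fixture(scope="session")
def toy_structure(toy_pdb):
    pdb_text, _ = toy_pdb
    return read_structure(pdb_text, {"A"}, {"B"})


@pytest.fixture(scope="session")
def uniform_catalog():
    return make_uniform_catalog()


@pytest.fixture(scope="session")
def single_weight():
    return CancerWeights("toy", {"S1": 1.0})


@pytest.fixture(scope="session")
def toy_gene():
    return make_toy_gene(12, seed=7)


def random_energy_matrix(rng, n_pos=4, n_rot=4, sd=2.0, template=0.0):
    """Synthetic pairwise energy matrix with N(0, sd) singles and pairs."""
    singles, pairs, pk = {}, {}, []
    for i in range(n_pos):
        keys = [(i, "X", r) for r in range(n_rot)]
        pk.append(keys)
        for k in keys:
            singles[k] = float(rng.normal(0, sd))
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            for ki, kj in itertools.product(pk[i], pk[j]):
                pairs[(ki, kj)] = float(rng.normal(0, sd))
    return EnergyMatrix(template, singles, pairs, pk)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
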