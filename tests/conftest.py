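import numpy as np
import pytest

from ogmap import ogdb
from ogmap.ogdb import TaxonomyTree
from ogmap.ontology import GoDag
from ogmap.simdb import SimConfig, simulate_bundle


@pytest.fixture(scope="session")
def small_sim():
    """A compact but fully structured synthetic database with ground truth."""
    return simulate_bundle(SimConfig(seed=11, n_families=12))


@pytest.fixture(scope="session")
def small_db(small_sim):
    return small_sim.db


@pytest.fixture()
def chain_taxonomy():
    """1 -> {2, 3}, 2 -> {4, 5}: two nested clades."""
    return TaxonomyTree(root=1, parent={2: 1, 3: 1, 4: 2, 5: 2}, names={1: "root"})


@pytest.fixture()
def diamond_dag():
    """d -> {b, c} -> a: two paths from d to the root a."""
    return GoDag(
        parents={
            "GO:0000001": set(),
            "GO:0000002": {"GO:0000001"},
            "GO:0000003": {"GO:0000001"},
            "GO:0000004": {"GO:0000002", "GO:0000003"},
        }
    )


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> TaxonomyTree:
    """Uniform random parent pointers: node i attaches to a random earlier node."""
    parent = {}
    for i in range(2, n_nodes + 1):
        parent[i] = int(rng.integers(1, i))
    return TaxonomyTree(root=1, parent=parent)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
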