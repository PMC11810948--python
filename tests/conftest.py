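import numpy as np
import pandas as pd
import pytest

import traitnet as tn
from traitnet.catalog import catalog_codes


@pytest.fixture(scope="session")
def hand_tree() -> tn.Phylogeny:
    """((A:1,B:1):1,C:2); — the worked three-tip example."""
    return tn.Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def tree8() -> tn.Phylogeny:
    return tn.simulate_tree(8, seed=11)


@pytest.fixture(scope="session")
def small_table() -> tn.TraitTable:
    """A deterministic 48-sample table with a planted offset and slope."""
    cfg = tn.SyntheticConfig(
        n_replicates=2,
        type_offsets={"LN": 2.0},
        elevation_slopes={"LDMC": 3.0},
        species_sd=0.0,
        seed=5,
    )
    table, _, _, _ = tn.generate_dataset(cfg)
    return table


@pytest.fixture(scope="session")
def codes() -> list[str]:
    return catalog_codes()


def make_survey(rows) -> tn.QuadratSurvey:
    return tn.QuadratSurvey(
        pd.DataFrame(rows, columns=["plot", "quadrat", "species", "count", "cover"])
    )


@pytest.fixture
def toy_survey() -> tn.QuadratSurvey:
    """Two quadrats, two species — the hand-computed IV example."""
    return make_survey(
        [
            ("p1", "q1", "A", 3, 0.30),
            ("p1", "q1", "B", 1, 0.10),
            ("p1", "q2", "A", 1, 0.20),
        ]
    )


def random_connected_graph(seed: int):
    """The seeded small-graph family used to audit community detection."""
    import networkx as nx

    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    while True:
        G = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(0, 2**31)))
        if nx.is_connected(G) and G.number_of_edges() > 0:
            return G
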