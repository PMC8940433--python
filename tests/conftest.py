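import networkx as nx
import pandas as pd
import pytest

from netpharm.synthetic import FixtureConfig


@pytest.fixture
def path3():
    """Path a-b-c."""
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c")])
    return g


@pytest.fixture
def k4():
    return nx.relabel_nodes(nx.complete_graph(4), {i: f"v{i}" for i in range(4)})


@pytest.fixture
def star4():
    """Star: center c with 3 leaves."""
    g = nx.Graph()
    g.add_edges_from([("c", "l1"), ("c", "l2"), ("c", "l3")])
    return g


@pytest.fixture
def small_cfg():
    """A scaled-down fixture config for fast generator tests."""
    return FixtureConfig(
        seed=42,
        n_herbs=3,
        compounds_per_herb=10,
        gene_universe_size=120,
        genes_per_disease_source=30,
        planted_modules=[(8, 1.0)],
        n_terms_per_category=5,
        n_samples_per_group=4,
    )


@pytest.fixture
def compound_rows():
    return pd.DataFrame(
        [
            ("C1", "herbA", "x", 30.0, 0.18),
            ("C2", "herbA", "y", 29.99, 0.9),
            ("C3", "herbB", "z", 80.0, 0.17),
            ("C1", "herbB", "x", 30.0, 0.18),
            ("C4", "herbB", "w", 55.0, 0.5),
        ],
        columns=["compound_id", "herb", "name", "OB", "DL"],
    )
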