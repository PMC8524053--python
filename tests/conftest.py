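import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet.abundance import AbundanceTable
from rhizonet.network import CoNetwork


def make_table(values, domains=None, compartment="Endo", mode="counts", otu_ids=None):
    """Small AbundanceTable from a 2-D array; defaults to all-bacterial."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    otus = otu_ids or [f"OTUB_{i:03d}" for i in range(n)]
    samples = [f"{compartment}_{j + 1:02d}" for j in range(m)]
    return AbundanceTable(
        values=pd.DataFrame(values, index=otus, columns=samples),
        domain=pd.Series(domains or ["bacteria"] * n, index=otus),
        compartment=pd.Series(compartment, index=samples),
        replicate=pd.Series(range(1, m + 1), index=samples),
        mode=mode,
    )


def graph_with(n_nodes: int, n_edges: int) -> nx.Graph:
    """Connected graph with exact node and edge counts (cycle plus chords)."""
    if n_edges < n_nodes:
        raise ValueError("need n_edges >= n_nodes for the cycle construction")
    g = nx.cycle_graph(n_nodes)
    extra = (
        pair
        for pair in itertools.combinations(range(n_nodes), 2)
        if not g.has_edge(*pair)
    )
    for _ in range(n_edges - n_nodes):
        g.add_edge(*next(extra))
    assert g.number_of_edges() == n_edges
    return g


def as_conetwork(graph: nx.Graph, st: float = 0.8, domains=None) -> CoNetwork:
    """Wrap a bare graph as a CoNetwork with default edge/node attributes."""
    g = graph.copy()
    for u, v in g.edges:
        du = domains[u] if domains else "bacteria"
        dv = domains[v] if domains else "bacteria"
        g[u][v].setdefault("r", st)
        g[u][v].setdefault("sign", 1)
        g[u][v].setdefault("interdomain", du != dv)
    for node in g.nodes:
        g.nodes[node].setdefault("domain", domains[node] if domains else "bacteria")
    return CoNetwork(graph=g, st=st)


@pytest.fixture
def small_counts_table():
    rng = np.random.default_rng(42)
    return make_table(rng.integers(0, 50, size=(12, 12)))
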