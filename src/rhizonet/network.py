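"""Co-occurrence network construction and topology summaries.

An edge connects two OTUs whenever the absolute correlation of their
relative abundances reaches the similarity threshold St; the signed
correlation is kept as an edge attribute, and each edge is flagged
intra- or inter-domain depending on whether its endpoints are both
bacterial/fungal or one of each.  Isolated OTUs are not counted as nodes,
matching the convention of molecular-ecological-network reporting where
node counts fall well below the number of filtered OTUs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .rmt import CorrelationMatrix, threshold_matrix

NETWORK_KINDS = ("bacterial", "fungal", "BFA")


@dataclass
class CoNetwork:
    """Undirected signed co-occurrence network over OTU nodes.

    ``graph`` carries node attribute ``domain`` and edge attributes ``r``
    (signed correlation), ``sign`` (+1/-1), and ``interdomain`` (bool).
    """

    graph: nx.Graph
    st: float
    kind: str = "BFA"
    compartment: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class NetworkSummary:
    n_nodes: int
    n_edges: int
    avg_connectivity: float
    avg_clustering: float
    avg_geodesic: float
    powerlaw_r2: float
    modularity: float | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def build_network(
    corr: CorrelationMatrix,
    st: float,
    domains: pd.Series | dict,
    kind: str = "BFA",
    compartment: str | None = None,
) -> CoNetwork:
    """Build the network with an edge for every OTU pair with ``|r| >= st``.

    Isolated (degree-0) OTUs are dropped.  ``domains`` maps OTU id to
    ``bacteria``/``fungi``.
    """
    if not 0 < st <= 1:
        raise ValueError(f"st must be in (0, 1], got {st}")
    if kind not in NETWORK_KINDS:
        raise ValueError(f"unknown network kind {kind!r}")
    domains = pd.Series(domains)
    m = threshold_matrix(corr, st)
    np.fill_diagonal(m, 0.0)
    g = nx.Graph()
    rows, cols = np.nonzero(np.triu(m, k=1))
    for i, j in zip(rows, cols):
        u, v = corr.otu_ids[i], corr.otu_ids[j]
        r = float(m[i, j])
        g.add_edge(
            u,
            v,
            r=r,
            sign=1 if r > 0 else -1,
            interdomain=bool(domains[u] != domains[v]),
        )
    nx.set_node_attributes(g, {node: domains[node] for node in g.nodes}, "domain")
    return CoNetwork(graph=g, st=st, kind=kind, compartment=compartment)


def degree_powerlaw_r2(graph: nx.Graph) -> float:
    """R^2 of the log10-log10 least-squares line through the degree-frequency histogram.

    Degrees with zero frequency are skipped; with fewer than three distinct
    degrees the line fits exactly and R^2 is 1 by convention.
    """
    degrees = np.array([d for _, d in graph.degree()])
    if degrees.size == 0:
        return float("nan")
    ks, freqs = np.unique(degrees[degrees > 0], return_counts=True)
    if ks.size <= 2:
        return 1.0
    fit = stats.linregress(np.log10(ks), np.log10(freqs))
    return float(fit.rvalue**2)


def summarize(net: CoNetwork) -> NetworkSummary:
    """Topology summary: average connectivity 2E/N, mean local clustering,
    mean geodesic distance on the giant component, and the power-law fit R^2.
    """
    g = net.graph
    n, e = g.number_of_nodes(), g.number_of_edges()
    if n < 1:
        raise ValueError("cannot summarize an empty network")
    avg_k = 2.0 * e / n
    clustering = float(np.mean(list(nx.clustering(g).values())))  # degree-1 nodes count as 0
    giant = g.subgraph(max(nx.connected_components(g), key=len))
    if giant.number_of_nodes() > 1:
        geodesic = nx.average_shortest_path_length(giant)
    else:
        geodesic = float("nan")
    return NetworkSummary(
        n_nodes=n,
        n_edges=e,
        avg_connectivity=avg_k,
        avg_clustering=clustering,
        avg_geodesic=float(geodesic),
        powerlaw_r2=degree_powerlaw_r2(g),
    )


def compare_connectivity(net_a: CoNetwork, net_b: CoNetwork):
    """Two-sided Fisher's exact test comparing edge densities of two networks.

    The 2x2 table counts realized versus unrealized edges out of the
    N(N-1)/2 possible pairs in each network.  Returns ``(odds_ratio, p)``.
    """
    for net in (net_a, net_b):
        if net.n_nodes < 2:
            raise ValueError("both networks need at least 2 nodes")
    tables = []
    for net in (net_a, net_b):
        possible = net.n_nodes * (net.n_nodes - 1) // 2
        tables.append([net.n_edges, possible - net.n_edges])
    odds, p = stats.fisher_exact(tables, alternative="two-sided")
    return float(odds), float(p)


def edge_domain_counts(net: CoNetwork) -> tuple[int, int]:
    """Count (intra-domain, inter-domain) edges; they sum to n_edges."""
    inter = sum(1 for _, _, d in net.graph.edges(data=True) if d["interdomain"])
    intra = net.n_edges - inter
    if inter == 0 and net.n_edges > 0:
        domains = {d for _, d in net.graph.nodes(data="domain")}
        if len(domains) == 1:
            warnings.warn("single-domain network: inter-domain count is trivially 0")
    return intra, inter


def write_edge_list(net: CoNetwork, path) -> None:
    """Write a plain tab-separated edge list (source, target, r, sign, interdomain)."""
    rows = [
        (u, v, d["r"], d["sign"], int(d["interdomain"]))
        for u, v, d in net.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "sign", "interdomain"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net: CoNetwork, path) -> None:
    """GraphML export loadable by Cytoscape/Gephi."""
    g = net.graph.copy()
    g.graph.update({"st": net.st, "kind": net.kind, "compartment": str(net.compartment)})
    nx.write_graphml(g, path)
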