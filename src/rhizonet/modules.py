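"""Module detection and Zi-Pi node-role classification.

Modules (communities) are found by Clauset-Newman-Moore greedy modularity
maximization; the quality of a partition is Newman's modularity
Q = sum_s (l_s/m - (d_s/2m)^2), with l_s the number of intra-module edges,
d_s the total degree of module s, and m the total edge count.  A network is
called modular when Q > 0.4.

Each node is then placed in the Zi-Pi plane: Zi is the within-module degree
z-score (how connected a node is relative to the other members of its
module) and Pi the participation coefficient (how evenly its links spread
over modules).  The classical thresholds partition the plane into network
hubs (Zi > 2.5 and Pi > 0.62), module hubs (Zi > 2.5 only), connectors
(Pi > 0.62 only) and peripherals; everything but a peripheral counts as a
keystone taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import CoNetwork

ZI_THRESHOLD = 2.5
PI_THRESHOLD = 0.62
MODULARITY_THRESHOLD = 0.4
ROLES = ("network_hub", "module_hub", "connector", "peripheral")


@dataclass
class ModulePartition:
    """node -> module id map plus the modularity of the partition."""

    assignment: dict
    modularity: float

    def modules(self) -> dict:
        """module id -> list of nodes."""
        out: dict = {}
        for node, mod in self.assignment.items():
            out.setdefault(mod, []).append(node)
        return out


def detect_modules(net: CoNetwork) -> ModulePartition:
    """Greedy (CNM) modularity maximization over the whole graph.

    Disconnected components are handled jointly, so one partition covers the
    network.  Module ids are assigned by decreasing module size with
    lexicographic tie-breaking, which makes repeated runs identical.
    """
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect modules in an edgeless network")
    communities = nx.community.greedy_modularity_communities(g)
    ordered = sorted(communities, key=lambda c: (-len(c), sorted(map(str, c))[0]))
    assignment = {node: i for i, comm in enumerate(ordered) for node in comm}
    q = modularity_score(net, assignment)
    return ModulePartition(assignment=assignment, modularity=q)


def modularity_score(net: CoNetwork, assignment: dict) -> float:
    """Newman's Q for an explicit node -> module assignment."""
    g = net.graph
    uncovered = [n for n in g.nodes if n not in assignment]
    if uncovered:
        raise ValueError(f"partition does not cover nodes: {uncovered[:5]}")
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an edgeless network")
    intra: dict = {}
    degree_sum: dict = {}
    for node in g.nodes:
        degree_sum[assignment[node]] = degree_sum.get(assignment[node], 0) + g.degree(node)
    for u, v in g.edges:
        if assignment[u] == assignment[v]:
            intra[assignment[u]] = intra.get(assignment[u], 0) + 1
    q = 0.0
    for mod, d_s in degree_sum.items():
        q += intra.get(mod, 0) / m - (d_s / (2 * m)) ** 2
    return float(q)


def zi_pi(net: CoNetwork, partition: ModulePartition) -> pd.DataFrame:
    """Within-module degree z-score (Zi) and participation coefficient (Pi).

    For node i in module s: kappa_i counts links to its own module and
    Zi = (kappa_i - mean kappa over s) / sd(kappa over s) with population
    sd (Zi = 0 when the sd is zero); Pi = 1 - sum_s (kappa_is / k_i)^2 over
    the links node i sends into every module s.
    """
    g = net.graph
    assignment = partition.assignment
    rows = []
    module_kappa: dict = {}
    per_node_links: dict = {}
    for node in g.nodes:
        links: dict = {}
        for nbr in g.neighbors(node):
            links[assignment[nbr]] = links.get(assignment[nbr], 0) + 1
        per_node_links[node] = links
        own = links.get(assignment[node], 0)
        module_kappa.setdefault(assignment[node], []).append(own)
    stats_ = {
        mod: (float(np.mean(k)), float(np.std(k)))  # population sd
        for mod, k in module_kappa.items()
    }
    for node in g.nodes:
        links = per_node_links[node]
        k_i = g.degree(node)
        own = links.get(assignment[node], 0)
        mean, sd = stats_[assignment[node]]
        zi = (own - mean) / sd if sd > 0 else 0.0
        pi = 1.0 - sum((c / k_i) ** 2 for c in links.values()) if k_i > 0 else 0.0
        rows.append((node, assignment[node], k_i, zi, pi))
    return pd.DataFrame(rows, columns=["node", "module", "degree", "zi", "pi"]).set_index("node")


def classify_roles(roles: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``role`` column from Zi/Pi with strict thresholds.

    Boundary-equal values (Zi = 2.5 or Pi = 0.62) fall to the less
    connected category, so peripherals absorb the boundaries.
    """
    out = roles.copy()
    hi_z = out["zi"] > ZI_THRESHOLD
    hi_p = out["pi"] > PI_THRESHOLD
    role = np.where(
        hi_z & hi_p, "network_hub", np.where(hi_z, "module_hub", np.where(hi_p, "connector", "peripheral"))
    )
    out["role"] = role
    return out


def keystone_report(
    roles: pd.DataFrame,
    domains: pd.Series | dict | None = None,
    taxonomy: pd.Series | dict | None = None,
    top_n: int = 3,
) -> pd.DataFrame:
    """All non-peripheral nodes (keystone taxa), flagged for the top-n degrees.

    Ties at the top-n degree boundary are all flagged (and marked as ties)
    rather than broken arbitrarily.
    """
    if "role" not in roles.columns:
        raise ValueError("classify_roles must run first")
    keystones = roles[roles["role"] != "peripheral"].copy()
    if domains is not None:
        keystones["domain"] = pd.Series(domains).reindex(keystones.index)
    if taxonomy is not None:
        keystones["taxonomy"] = pd.Series(taxonomy).reindex(keystones.index)
    keystones = keystones.sort_values("degree", ascending=False, kind="stable")
    if len(keystones) == 0:
        keystones["top_degree"] = pd.Series(dtype=bool)
        keystones["degree_tie"] = pd.Series(dtype=bool)
        return keystones
    degrees = keystones["degree"].to_numpy()
    cutoff = degrees[min(top_n, len(degrees)) - 1]
    top = keystones["degree"] >= cutoff
    keystones["top_degree"] = top
    keystones["degree_tie"] = top & (keystones["degree"] == cutoff) & (int(top.sum()) > top_n)
    return keystones


def module_composition(
    partition: ModulePartition, domains: pd.Series | dict, min_size: int = 15
) -> pd.DataFrame:
    """Bacterial/fungal make-up of every module larger than ``min_size`` nodes.

    The size filter is strict (a module of exactly ``min_size`` nodes is
    excluded); fractions sum to one within each reported module.
    """
    domains = pd.Series(domains)
    rows = []
    for mod, nodes in sorted(partition.modules().items()):
        if len(nodes) <= min_size:
            continue
        labels = domains.reindex(nodes)
        n_b = int((labels == "bacteria").sum())
        n_f = int((labels == "fungi").sum())
        total = n_b + n_f
        rows.append((mod, len(nodes), n_b, n_f, n_b / total, n_f / total))
    return pd.DataFrame(
        rows,
        columns=["module", "n_nodes", "n_bacteria", "n_fungi", "frac_bacteria", "frac_fungi"],
    ).set_index("module")


def is_modular(modularity: float, threshold: float = MODULARITY_THRESHOLD) -> bool:
    """Strict reading of the modular-structure rule: modular iff Q > 0.4."""
    return modularity > threshold
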