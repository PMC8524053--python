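"""Planted-structure recovery benchmarks for the whole pipeline.

These run the generator's default community through the full analysis chain
(prevalence filter, relative abundance, correlation, RMT threshold
selection, network construction, greedy module detection) and score how
well the detected modules match the planted ones by normalized mutual
information (NMI) over the planted-module members present in the network.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from sklearn.metrics import normalized_mutual_info_score

from . import abundance as ab
from . import modules as md
from . import network as nw
from . import rmt
from .synth import SyntheticScenario, generate_community


@dataclass
class RecoveryResult:
    seed: int
    selected_st: float
    n_nodes: int
    n_edges: int
    edge_fraction: float  # edges / possible pairs among correlated OTUs
    nmi: float
    modularity: float


def module_recovery(
    seed: int,
    corr_strength: float = 3.0,
    noise_sd: float = 0.2,
    dropout_prob: float = 0.0,
    scenario: SyntheticScenario | None = None,
) -> RecoveryResult:
    """Generate one community, run the pipeline, and score module recovery.

    With ``corr_strength=0`` nothing is planted; the NMI is reported as NaN
    and the interesting quantity is ``edge_fraction`` (how sparse the
    selected-threshold network is relative to all possible OTU pairs).
    """
    if scenario is None:
        scenario = SyntheticScenario()
    scenario = replace(
        scenario,
        seed=seed,
        corr_strength=corr_strength,
        noise_sd=noise_sd,
        dropout_prob=dropout_prob,
    )
    table, planted = generate_community(scenario)
    rel = ab.to_relative_abundance(ab.prevalence_filter(table, of_replicates=scenario.n_replicates))
    corr = rmt.correlation_matrix(rel)
    scan = rmt.select_threshold(corr)
    net = nw.build_network(corr, scan.selected_st, rel.domain, "BFA", scenario.compartment)
    n_corr = len(corr.otu_ids)
    possible = n_corr * (n_corr - 1) / 2
    if net.n_edges == 0:
        return RecoveryResult(seed, scan.selected_st, 0, 0, 0.0, float("nan"), float("nan"))
    partition = md.detect_modules(net)
    members = [
        node for node in net.graph.nodes if planted.get(node, 0) > 0
    ]
    if corr_strength > 0 and members:
        nmi = float(
            normalized_mutual_info_score(
                [planted[node] for node in members],
                [partition.assignment[node] for node in members],
            )
        )
    else:
        nmi = float("nan")
    return RecoveryResult(
        seed=seed,
        selected_st=scan.selected_st,
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        edge_fraction=net.n_edges / possible,
        nmi=nmi,
        modularity=partition.modularity,
    )
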