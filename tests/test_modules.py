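import networkx as nx
import numpy as np
import pandas as pd
import pytest

from rhizonet.modules import (
    classify_roles,
    detect_modules,
    is_modular,
    keystone_report,
    modularity_score,
    module_composition,
    zi_pi,
)

from conftest import as_conetwork


def two_triangles():
    return as_conetwork(nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3)))


def brute_force_zi_pi(graph, assignment):
    """Independent per-node link-count implementation of Zi and Pi."""
    out = {}
    modules = {}
    for node, mod in assignment.items():
        modules.setdefault(mod, []).append(node)
    for node in graph.nodes:
        counts = {}
        for other in graph.nodes:
            if other != node and graph.has_edge(node, other):
                counts[assignment[other]] = counts.get(assignment[other], 0) + 1
        k = sum(counts.values())
        kappas = [
            sum(1 for other in graph.neighbors(member) if assignment[other] == assignment[member])
            for member in modules[assignment[node]]
        ]
        mean, sd = np.mean(kappas), np.std(kappas)
        own = counts.get(assignment[node], 0)
        zi = (own - mean) / sd if sd > 0 else 0.0
        pi = 1 - sum((c / k) ** 2 for c in counts.values()) if k else 0.0
        out[node] = (zi, pi)
    return out


class TestDetectModules:
    def test_two_disjoint_triangles(self):
        partition = detect_modules(two_triangles())
        assert partition.modularity == pytest.approx(0.5)
        groups = partition.modules()
        assert sorted(sorted(v) for v in groups.values()) == [[0, 1, 2], [3, 4, 5]]

    def test_complete_graph_single_module(self):
        partition = detect_modules(as_conetwork(nx.complete_graph(8)))
        assert len(partition.modules()) == 1
        assert partition.modularity == pytest.approx(0.0)

    def test_planted_two_cliques_recovered_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(20), nx.complete_graph(20))
        g.add_edge(0, 20)
        partition = detect_modules(as_conetwork(g))
        left = {n for n, m in partition.assignment.items() if m == partition.assignment[0]}
        assert left == set(range(20))

    def test_edgeless_rejected(self):
        empty = as_conetwork(nx.empty_graph(4))
        with pytest.raises(ValueError, match="edgeless"):
            detect_modules(empty)

    def test_deterministic_assignment(self):
        net = as_conetwork(nx.gnm_random_graph(40, 120, seed=5))
        a = detect_modules(net).assignment
        b = detect_modules(net).assignment
        assert a == b


class TestModularityScore:
    def test_single_module_is_zero(self):
        net = as_conetwork(nx.gnm_random_graph(10, 20, seed=1))
        assert modularity_score(net, {n: 0 for n in net.graph.nodes}) == pytest.approx(0.0)

    def test_correct_triangle_split_is_half(self):
        net = two_triangles()
        split = {n: (0 if n < 3 else 1) for n in net.graph.nodes}
        assert modularity_score(net, split) == pytest.approx(0.5)

    def test_perturbed_split_scores_lower(self):
        net = two_triangles()
        worse = {0: 0, 1: 0, 2: 1, 3: 1, 4: 1, 5: 1}
        assert modularity_score(net, worse) < 0.5

    def test_matches_networkx_on_random_partitions(self):
        rng = np.random.default_rng(3)
        net = as_conetwork(nx.gnm_random_graph(25, 60, seed=3))
        for _ in range(5):
            assignment = {n: int(rng.integers(0, 4)) for n in net.graph.nodes}
            groups = {}
            for n, m in assignment.items():
                groups.setdefault(m, set()).add(n)
            expected = nx.community.modularity(net.graph, groups.values())
            assert modularity_score(net, assignment) == pytest.approx(expected, abs=1e-12)

    def test_uncovered_node_rejected(self):
        net = two_triangles()
        with pytest.raises(ValueError, match="cover"):
            modularity_score(net, {0: 0})


class TestZiPi:
    def test_all_internal_links_give_zero_pi(self):
        net = two_triangles()
        partition = detect_modules(net)
        roles = zi_pi(net, partition)
        assert (roles["pi"] == 0).all()

    def test_four_way_connector_pi(self):
        # hub node 0 with one link into each of four 3-cliques
        g = nx.Graph()
        assignment = {0: 0}
        for m in range(4):
            members = [1 + 3 * m, 2 + 3 * m, 3 + 3 * m]
            for a in members:
                for b in members:
                    if a < b:
                        g.add_edge(a, b)
                assignment[a] = m + 1
            g.add_edge(0, members[0])
        net = as_conetwork(g)
        from rhizonet.modules import ModulePartition

        roles = zi_pi(net, ModulePartition(assignment=assignment, modularity=0.0))
        assert roles.loc[0, "pi"] == pytest.approx(0.75)

    def test_matches_brute_force_on_fixture(self):
        g = nx.gnm_random_graph(12, 28, seed=9)
        assignment = {n: n % 3 for n in g.nodes}
        from rhizonet.modules import ModulePartition

        net = as_conetwork(g)
        roles = zi_pi(net, ModulePartition(assignment=assignment, modularity=0.0))
        oracle = brute_force_zi_pi(g, assignment)
        for node, (zi, pi) in oracle.items():
            assert roles.loc[node, "zi"] == pytest.approx(zi, abs=1e-10)
            assert roles.loc[node, "pi"] == pytest.approx(pi, abs=1e-10)

    def test_standardization_and_link_conservation(self):
        net = as_conetwork(nx.gnm_random_graph(30, 90, seed=2))
        partition = detect_modules(net)
        roles = zi_pi(net, partition)
        for mod, group in roles.groupby("module"):
            if len(group) >= 2 and group["zi"].abs().sum() > 0:
                assert group["zi"].mean() == pytest.approx(0.0, abs=1e-10)
                assert group["zi"].std(ddof=0) == pytest.approx(1.0, abs=1e-10)


class TestClassifyRoles:
    @pytest.mark.parametrize(
        "zi,pi,expected",
        [
            (3.0, 0.10, "module_hub"),
            (1.0, 0.70, "connector"),
            (3.0, 0.70, "network_hub"),
            (0.0, 0.0, "peripheral"),
            (2.5, 0.62, "peripheral"),  # boundary values are strict
        ],
    )
    def test_threshold_table(self, zi, pi, expected):
        roles = classify_roles(pd.DataFrame({"zi": [zi], "pi": [pi], "degree": [5], "module": [0]}))
        assert roles["role"].iloc[0] == expected

    def test_every_node_gets_exactly_one_role(self):
        net = as_conetwork(nx.gnm_random_graph(40, 100, seed=8))
        roles = classify_roles(zi_pi(net, detect_modules(net)))
        assert roles["role"].isin(["network_hub", "module_hub", "connector", "peripheral"]).all()
        assert len(roles) == net.n_nodes


class TestKeystoneReport:
    def _roles(self, rows):
        df = pd.DataFrame(rows, columns=["node", "module", "degree", "zi", "pi", "role"])
        return df.set_index("node")

    def test_all_peripheral_gives_empty_report(self):
        roles = self._roles([("a", 0, 3, 0.1, 0.1, "peripheral")])
        assert keystone_report(roles).empty

    def test_fixture_ordering_and_top_flag(self):
        roles = self._roles(
            [
                ("hub1", 0, 9, 3.0, 0.1, "module_hub"),
                ("hub2", 1, 7, 2.8, 0.2, "module_hub"),
                ("conn", 2, 5, 0.5, 0.7, "connector"),
                ("per", 0, 12, 0.2, 0.1, "peripheral"),
            ]
        )
        report = keystone_report(roles)
        assert list(report.index) == ["hub1", "hub2", "conn"]
        assert report["top_degree"].all()
        assert not report["degree_tie"].any()

    def test_tie_at_rank_three_reported(self):
        roles = self._roles(
            [
                ("a", 0, 9, 3.0, 0.1, "module_hub"),
                ("b", 1, 7, 3.0, 0.1, "module_hub"),
                ("c", 2, 5, 0.5, 0.7, "connector"),
                ("d", 3, 5, 0.5, 0.7, "connector"),
            ]
        )
        report = keystone_report(roles, top_n=3)
        assert report["top_degree"].sum() == 4
        assert report.loc[["c", "d"], "degree_tie"].all()


class TestModuleComposition:
    def _partition(self, sizes):
        from rhizonet.modules import ModulePartition

        assignment = {}
        i = 0
        for mod, size in enumerate(sizes):
            for _ in range(size):
                assignment[f"n{i}"] = mod
                i += 1
        return ModulePartition(assignment=assignment, modularity=0.5)

    def test_fractions_and_strict_size_filter(self):
        partition = self._partition([20, 15])
        domains = {f"n{i}": ("fungi" if i < 10 else "bacteria") for i in range(35)}
        comp = module_composition(partition, domains, min_size=15)
        assert list(comp.index) == [0]  # the 15-node module is excluded (strict)
        assert comp.loc[0, "frac_fungi"] == pytest.approx(0.5)
        assert comp.loc[0, "frac_bacteria"] == pytest.approx(0.5)

    def test_single_domain_module(self):
        partition = self._partition([20])
        domains = {f"n{i}": "fungi" for i in range(20)}
        comp = module_composition(partition, domains)
        assert comp.loc[0, "frac_fungi"] == 1.0


@pytest.mark.parametrize("q,expected", [(0.5, True), (0.4, False), (0.0, False)])
def test_modularity_flag_is_strict(q, expected):
    assert is_modular(q) is expected
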