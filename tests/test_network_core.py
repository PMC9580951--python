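"""Network construction, topology summaries, node metrics, hubs and power-law fit."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from brdnet import network_core as nc
from brdnet.exceptions import DegenerateTableError, FitUndefinedError
from brdnet.interaction_io import InteractionCorpus, InteractionRecord
from brdnet.synthetic_data import SyntheticSpec, generate_network

from conftest import nx_to_network, random_er_graph


def corpus_of(*pairs):
    return InteractionCorpus([InteractionRecord(a, b) for a, b in pairs])


class TestBuild:
    def test_canonical_collapse_drops_self_loops(self):
        net = nc.build_network(corpus_of(("A", "B"), ("B", "A"), ("A", "A")))
        assert (net.n_nodes, net.n_edges, net.n_self_loops) == (2, 1, 0)

    def test_keep_self_loops(self):
        net = nc.build_network(
            corpus_of(("A", "B"), ("B", "A"), ("A", "A")), keep_self_loops=True
        )
        assert (net.n_nodes, net.n_edges, net.n_self_loops) == (2, 1, 1)
        net.audit()

    def test_empty_corpus_gives_empty_network(self):
        assert nc.build_network(InteractionCorpus()).n_nodes == 0

    def test_degree_sum_handshake(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            graph = random_er_graph(rng, n_max=30)
            net = nx_to_network(graph)
            assert sum(net.degree(n) for n in net.nodes) == 2 * net.n_edges


class TestGraphml:
    def test_graphml_readable_by_reference_library(self, tmp_path):
        net = nc.build_network(
            corpus_of(("A", "B"), ("B", "C"), ("C", "C")), keep_self_loops=True, weighted=True
        )
        path = tmp_path / "net.graphml"
        nc.write_graphml(net, path)
        back = nx.read_graphml(path)
        assert set(back.nodes) == set(net.nodes)
        assert {tuple(sorted(e)) for e in back.edges} == {("A", "B"), ("B", "C"), ("C", "C")}
        assert back.edges[("A", "B")]["weight"] == 1.0


class TestFamilyExtraction:
    def test_star_center_family_returns_whole_star(self, star4):
        sub = nc.extract_family_subnetwork(star4, {"A"})
        assert sub.n_nodes == 5 and sub.n_edges == 4

    def test_triangle_includes_interactor_interactor_edge(self, triangle):
        sub = nc.extract_family_subnetwork(triangle, {"A"})
        assert sub.has_edge("B", "C")

    def test_empty_family_rejected(self, triangle):
        with pytest.raises(ValueError):
            nc.extract_family_subnetwork(triangle, set())

    def test_matches_brute_force_induced_subgraph(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            graph = random_er_graph(rng, n_max=40)
            net = nx_to_network(graph)
            family_int = set(rng.choice(list(graph.nodes), size=4, replace=False))
            closure = set(family_int)
            for f in family_int:
                closure |= set(graph.neighbors(f))
            expected = graph.subgraph(closure)
            sub = nc.extract_family_subnetwork(net, {str(f) for f in family_int})
            assert sub.n_nodes == expected.number_of_nodes()
            expected_edges = {tuple(sorted((str(u), str(v)))) for u, v in expected.edges()}
            assert set(sub.edges()) == expected_edges

    def test_family_family_weights_and_loops(self):
        corpus = corpus_of(("A", "B"), ("A", "B"), ("A", "A"), ("A", "X"))
        net = nc.build_network(corpus, keep_self_loops=True)
        famfam = nc.extract_family_family_network(net, {"A", "B", "C"}, corpus)
        assert famfam.nodes == ["A", "B"]
        assert famfam.weights[("A", "B")] == 2
        assert famfam.self_loops == {"A"}

    def test_family_family_empty_when_no_intra_pairs(self):
        corpus = corpus_of(("A", "X"), ("B", "Y"))
        net = nc.build_network(corpus)
        assert nc.extract_family_family_network(net, {"A", "B"}, corpus).n_nodes == 0


class TestTopology:
    def test_path3_closed_forms(self, path3):
        t = nc.summarize_topology(path3)
        assert t.density == pytest.approx(0.667, abs=5e-4)
        assert (t.radius, t.diameter) == (1, 2)
        assert t.average_shortest_path == pytest.approx(4 / 3)
        assert t.average_clustering == 0.0
        assert t.n_components == 1

    def test_density_and_radius_bounds_match_reference_on_random_graphs(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            graph = random_er_graph(rng, n_max=40)
            net = nx_to_network(graph)
            t = nc.summarize_topology(net)
            assert t.density == pytest.approx(nx.density(graph), abs=1e-12)
            comps = list(nx.connected_components(graph))
            largest = max(comps, key=len)
            if len(largest) > 1:
                sub = graph.subgraph(largest)
                assert t.radius == nx.radius(sub)
                assert t.diameter == nx.diameter(sub)
                assert t.radius <= t.diameter <= 2 * t.radius
            # average path over connected pairs only
            total, count = 0, 0
            for comp in comps:
                sub = graph.subgraph(comp)
                for src, dist in nx.all_pairs_shortest_path_length(sub):
                    total += sum(dist.values())
                    count += len(dist) - 1
            if count:
                assert t.average_shortest_path == pytest.approx(total / count)
            assert t.n_components == len(comps)

    def test_clustering_mean_excludes_low_degree_by_default(self):
        net = nc.build_network(corpus_of(("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")))
        t = nc.summarize_topology(net)
        ref = nx.clustering(nx.Graph([("A", "B"), ("B", "C"), ("A", "C"), ("C", "D")]))
        expected = np.mean([ref[n] for n in "ABC"])  # D has degree 1: excluded
        assert t.average_clustering == pytest.approx(expected)
        t0 = nc.summarize_topology(net, degree_lt2_as_zero=True)
        assert t0.average_clustering == pytest.approx(np.mean(list(ref.values())))

    def test_compactness_rule(self):
        assert nc.compactness_class(37, 121) == "dense"
        assert nc.compactness_class(100, 99) == "sparse"  # k < 1
        assert nc.compactness_class(10, 10) == "sparse"  # E = V exactly

    def test_single_node_distances_undefined(self):
        net = nc.Network()
        net.add_node("A")
        t = nc.summarize_topology(net)
        assert t.radius is None and t.diameter is None and t.average_shortest_path is None


class TestNodeMetrics:
    def test_star_closed_forms(self, star4):
        m = nc.node_metrics(star4).frame
        assert m.loc["A", "degree"] == 4
        assert m.loc["A", "betweenness"] == 6  # C(4,2) leaf pairs
        assert m.loc["A", "eccentricity"] == 1
        assert all(m.loc[list("BCDE"), "betweenness"] == 0)
        assert m.loc["A", "eigenvector"] == pytest.approx(1.0)

    def test_k4_cores_and_clustering(self, k4):
        m = nc.node_metrics(k4).frame
        assert (m["core_number"] == 3).all()
        assert (m["local_clustering"] == 1.0).all()

    def test_all_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            graph = random_er_graph(rng, n_max=25)
            net = nx_to_network(graph)
            m = nc.node_metrics(net).frame
            n = graph.number_of_nodes()
            bc = nx.betweenness_centrality(graph, normalized=False)
            core = nx.core_number(graph)
            clust = nx.clustering(graph)
            for v in graph.nodes:
                key = str(v)
                assert m.loc[key, "degree"] == graph.degree(v)
                assert m.loc[key, "betweenness"] == pytest.approx(bc[v], abs=1e-9)
                assert m.loc[key, "core_number"] == core[v]
                dist = nx.single_source_shortest_path_length(graph, v)
                penalty = sum(dist.values()) + (n - len(dist)) * n
                assert m.loc[key, "closeness"] == pytest.approx(1 / penalty, rel=1e-12)
                if graph.degree(v) < 2:
                    assert math.isnan(m.loc[key, "local_clustering"])
                else:
                    assert m.loc[key, "local_clustering"] == pytest.approx(clust[v])

    def test_core_number_invariant_under_relabeling(self):
        rng = np.random.default_rng(31)
        graph = random_er_graph(rng, n_max=30)
        net = nx_to_network(graph)
        cores = nc.node_metrics(net).frame["core_number"]
        mapping = {v: f"X{v}" for v in graph.nodes}
        net2 = nx_to_network(nx.relabel_nodes(graph, mapping))
        cores2 = nc.node_metrics(net2).frame["core_number"]
        for v in graph.nodes:
            assert cores[str(v)] == cores2[f"X{v}"]

    def test_node_removal_never_raises_core_number(self):
        rng = np.random.default_rng(32)
        graph = random_er_graph(rng, n_max=20)
        net = nx_to_network(graph)
        cores = nc.node_metrics(net).frame["core_number"]
        victim = net.nodes[0]
        reduced = net.subgraph(set(net.nodes) - {victim})
        if reduced.n_nodes:
            cores2 = nc.node_metrics(reduced).frame["core_number"]
            assert all(cores2[v] <= cores[v] for v in reduced.nodes)


class TestHubs:
    def _metrics_from_degrees(self, degrees: dict) -> nc.NodeMetrics:
        return nc.NodeMetrics(frame=pd.DataFrame({"degree": pd.Series(degrees)}))

    def test_strictly_above_mean(self):
        m = self._metrics_from_degrees({"A": 1, "B": 1, "C": 4})
        report = nc.classify_hubs(m, {"A"})
        assert report.mean_degree == 2 and report.hubs == frozenset({"C"})

    def test_equal_degrees_give_zero_hubs_and_degenerate_table(self):
        m = self._metrics_from_degrees({"A": 2, "B": 2, "C": 2})
        report = nc.classify_hubs(m, {"A"})
        assert not report.hubs and report.degenerate and report.test is None

    def test_group_threshold_consistency_with_direct_chisquare(self):
        from brdnet.stats import chi_square_2x2

        degrees = {f"N{i}": d for i, d in enumerate([1, 2, 3, 10, 11, 12, 2, 9])}
        m = self._metrics_from_degrees(degrees)
        family = {"N3", "N4", "N5"}
        result = nc.group_threshold_chisquare(m, family, "degree", 8)
        above = {n for n, d in degrees.items() if d > 8}
        table = (
            (len(above & family), len(family - above)),
            (len(above - family), len(set(degrees) - family - above)),
        )
        direct = chi_square_2x2(table)
        assert result.statistic == pytest.approx(direct.statistic)

    def test_null_threshold_large_sample_p_near_one(self):
        rng = np.random.default_rng(17)
        degrees = {f"N{i}": int(d) for i, d in enumerate(rng.integers(1, 100, 4000))}
        m = self._metrics_from_degrees(degrees)
        family = set(list(degrees)[:2000])  # arbitrary split, same distribution
        result = nc.group_threshold_chisquare(m, family, "degree", 50)
        assert result.p_value > 0.05

    def test_degenerate_margin_signalled(self):
        m = self._metrics_from_degrees({"A": 1, "B": 2})
        with pytest.raises(DegenerateTableError):
            nc.group_threshold_chisquare(m, {"A"}, "degree", 100)


class TestPowerLaw:
    def test_recovery_on_zeta_samples(self):
        for seed in (1, 2, 3):
            rng = np.random.default_rng(seed)
            sample = nc.sample_discrete_power_law(2.5, 1, 10000, rng)
            fit = nc.fit_power_law(sample)
            assert fit.alpha == pytest.approx(2.5, abs=0.1)

    def test_constant_degrees_undefined(self):
        with pytest.raises(FitUndefinedError):
            nc.fit_power_law([5] * 100)

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError):
            nc.fit_power_law([1, 2, 3, 4, 5] * 10)

    def test_preferential_attachment_consistency(self):
        in_band = 0
        high_p = 0
        for seed in range(10):
            net, _ = generate_network(
                SyntheticSpec(n_nodes=10000, family_degree_boost=1.0, seed=seed)
            )
            fit = nc.fit_power_law([net.degree(n) for n in net.nodes])
            in_band += 2.5 <= fit.alpha <= 3.5
            high_p += fit.p_value > 0.05
        assert in_band == 10
        assert high_p >= 9

    def test_bootstrap_pvalue_agrees_qualitatively(self):
        rng = np.random.default_rng(4)
        sample = nc.sample_discrete_power_law(2.5, 1, 2000, rng)
        fit = nc.fit_power_law(sample, bootstrap_reps=50, seed=0)
        assert fit.p_value > 0.05  # genuine power-law sample not rejected
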