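"""Co-occurrence network construction, topology, robustness and modularity."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ecoassembly.core import CommunityTable, ValidationError, relative_abundance
from ecoassembly.network import (
    CoNetwork,
    build_network,
    edge_census,
    enrichment_labels,
    erdos_renyi_baseline,
    filter_min_sequences,
    modularity_partition,
    natural_connectivity,
    network_metrics,
    node_metrics,
    powerlaw_fit_r2,
    robustness_curve,
)


def _as_net(G):
    return CoNetwork(G, n_tested=G.number_of_nodes())


def _graph(edges):
    G = nx.Graph()
    for a, b in edges:
        G.add_edge(a, b, rho=1.0, p=0.0, sign="positive")
    return _as_net(G)


class TestFilterMinSequences:
    def test_threshold_is_strictly_more_than_twenty(self):
        counts = np.array([[21, 0], [20, 0], [10, 11], [5, 5]])
        t = CommunityTable(["keep", "drop", "keep2", "drop2"], ["s1", "s2"],
                           counts, {"s1": "g", "s2": "g"})
        out = filter_min_sequences(t)
        assert out.otu_ids == ["keep", "keep2"]

    def test_identity_when_all_pass(self, table_factory):
        t = table_factory(n_otus=10, n_samples=6, seed=1, max_count=100)
        t.counts += 10
        assert filter_min_sequences(t).otu_ids == t.otu_ids

    def test_monotone_in_counts(self, table_factory):
        t = table_factory(n_otus=30, n_samples=5, seed=2, max_count=12)
        kept_before = set(filter_min_sequences(t, min_total=10).otu_ids)
        t2 = CommunityTable(t.otu_ids, t.sample_ids, t.counts + 1,
                            t.sample_groups)
        kept_after = set(filter_min_sequences(t2, min_total=10).otu_ids)
        assert kept_before <= kept_after


class TestEnrichmentLabels:
    def _two_group_table(self, counts):
        n, s = counts.shape
        half = s // 2
        sample_ids = [f"m{i}" for i in range(half)] + [f"i{i}" for i in range(s - half)]
        groups = {x: ("monsoon" if x.startswith("m") else "intermonsoon")
                  for x in sample_ids}
        return CommunityTable([f"o{i}" for i in range(n)], sample_ids, counts, groups)

    def test_fully_separated_otu_labelled(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(50, 60, size=(3, 24))
        counts[0, :12] = rng.integers(500, 600, 12)   # high in monsoon
        counts[0, 12:] = rng.integers(1, 10, 12)
        t = self._two_group_table(counts)
        labels = enrichment_labels(t)
        assert labels["o0"] == "monsoon"

    def test_identical_distribution_is_others(self):
        counts = np.tile(np.array([[7], [3]]), (1, 24))
        t = self._two_group_table(counts)
        assert set(enrichment_labels(t)) == {"Others"}

    def test_direction_flips_with_groups(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(50, 60, size=(2, 24))
        counts[0, :12] += 500
        t = self._two_group_table(counts)
        swapped = CommunityTable(
            t.otu_ids, t.sample_ids, t.counts,
            {s: ("intermonsoon" if g == "monsoon" else "monsoon")
             for s, g in t.sample_groups.items()},
        )
        assert enrichment_labels(t)["o0"] == "monsoon"
        assert enrichment_labels(swapped)["o0"] == "intermonsoon"

    def test_requires_two_groups(self, table_factory):
        t = table_factory(groups=("one",))
        with pytest.raises(ValidationError):
            enrichment_labels(t)


class TestBuildNetwork:
    def _relabund(self, matrix):
        n, s = matrix.shape
        sample_ids = [f"s{j}" for j in range(s)]
        return relative_abundance(
            CommunityTable([f"o{i}" for i in range(n)], sample_ids,
                           matrix, {x: "g" for x in sample_ids})
        )

    def test_perfect_correlations_signed_edges(self):
        rng = np.random.default_rng(3)
        base = rng.integers(1, 100, 24)
        counts = np.vstack([base, base * 2, base.max() + 1 - base,
                            rng.integers(1, 100, 24)])
        net = build_network(self._relabund(counts))
        assert net.graph.has_edge("o0", "o1")
        assert net.graph.edges["o0", "o1"]["sign"] == "positive"
        assert net.graph.has_edge("o0", "o2")
        assert net.graph.edges["o0", "o2"]["sign"] == "negative"

    def test_moderate_correlation_no_edge(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=24)
        y = 0.5 * x + rng.normal(size=24)  # rho well below 0.8
        counts = np.abs(np.vstack([x, y, rng.normal(size=24)]) * 100).astype(int) + 1
        net = build_network(self._relabund(counts))
        assert not net.graph.has_edge("o0", "o1")

    def test_isolated_nodes_tracked_not_graphed(self):
        rng = np.random.default_rng(5)
        base = rng.integers(1, 100, 24)
        counts = np.vstack([base, base + 1,
                            rng.integers(1, 100, size=(12, 24))])
        net = build_network(self._relabund(counts))
        assert net.n_tested == 14
        # graph nodes and isolated nodes partition the tested set
        assert set(net.isolated) | set(net.graph.nodes) == {
            f"o{i}" for i in range(14)
        }
        assert not set(net.isolated) & set(net.graph.nodes)
        assert len(net.isolated) > 0
        assert net.graph.has_edge("o0", "o1")

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(6)
        counts = rng.integers(1, 100, size=(12, 24))
        ra = self._relabund(counts)
        loose = build_network(ra, r_threshold=0.3, p_threshold=0.3)
        tight = build_network(ra, r_threshold=0.6, p_threshold=0.3)
        assert set(tight.graph.edges) <= set(loose.graph.edges)


# -- independent brute-force implementations for the oracle test -----------


def _brute_force_metrics(G):
    nodes = sorted(G.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((n, n))
    for a, b in G.edges:
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = 1
    # Floyd-Warshall distances
    dist = np.where(A > 0, 1.0, np.inf)
    np.fill_diagonal(dist, 0)
    for k in range(n):
        dist = np.minimum(dist, dist[:, [k]] + dist[[k], :])
    # shortest-path counts by dynamic programming on distance layers
    sigma = np.zeros((n, n))
    for s in range(n):
        sigma[s, s] = 1
        for d in range(1, n):
            for t in range(n):
                if dist[s, t] == d:
                    sigma[s, t] = sum(
                        sigma[s, u] for u in range(n)
                        if A[u, t] and dist[s, u] == d - 1
                    )
    betw = np.zeros(n)
    for v in range(n):
        for s in range(n):
            for t in range(n):
                if s < t and s != v and t != v and np.isfinite(dist[s, t]):
                    if dist[s, v] + dist[v, t] == dist[s, t]:
                        betw[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    comp_size = np.array([np.isfinite(dist[v]).sum() for v in range(n)])
    denom = (comp_size - 1) * (comp_size - 2) / 2
    betw = np.where(denom > 0, betw / np.maximum(denom, 1), 0.0)
    close = np.array(
        [
            (comp_size[v] - 1) / dist[v][np.isfinite(dist[v])].sum()
            if comp_size[v] > 1 else 0.0
            for v in range(n)
        ]
    )
    # eigenvector by power iteration on A + I (handles bipartite spectra)
    vec = np.ones(n)
    for _ in range(20000):
        nxt = (A + np.eye(n)) @ vec
        vec = nxt / np.linalg.norm(nxt)
    degree = A.sum(axis=1)
    finite = dist[np.isfinite(dist) & (dist > 0)]
    return {
        "degree": degree,
        "betweenness": betw,
        "closeness": close,
        "eigenvector": np.abs(vec),
        "diameter": finite.max(),
        "apl": finite.mean(),
        "clustering": np.mean(
            [
                (A[np.ix_(nb, nb)].sum() / 2) / (len(nb) * (len(nb) - 1) / 2)
                if len(nb := np.flatnonzero(A[v])) >= 2 else 0.0
                for v in range(n)
            ]
        ),
    }


class TestMetricOracle:
    def test_path_graph_hand_values(self):
        net = _graph([("A", "B"), ("B", "C")])
        m = node_metrics(net)
        assert list(m.loc[["A", "B", "C"], "degree"]) == [1, 2, 1]
        assert m.loc["B", "betweenness"] == pytest.approx(1.0)
        assert m.loc["A", "closeness"] == pytest.approx(2 / 3)
        g = network_metrics(net)
        assert g.connectance == pytest.approx(2 / 3)
        assert g.diameter == 2
        assert g.average_path_length == pytest.approx(4 / 3)
        assert g.clustering_coefficient == 0.0

    def test_complete_graph_symmetric(self):
        net = _graph([(a, b) for a in "abcd" for b in "abcd" if a < b])
        m = node_metrics(net)
        assert np.allclose(m.betweenness, 0.0)
        assert np.allclose(m.eigenvector, m.eigenvector.iloc[0])
        g = network_metrics(net)
        assert g.connectance == 1.0
        assert g.clustering_coefficient == 1.0

    def test_fifty_random_graphs_match_brute_force(self):
        rng = np.random.default_rng(77)
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 9))
            G = nx.gnp_random_graph(n, 0.5, seed=int(rng.integers(2**31)))
            if not nx.is_connected(G) or G.number_of_edges() < 3:
                continue
            G = nx.relabel_nodes(G, {i: f"n{i}" for i in G.nodes})
            for a, b in G.edges:
                G.edges[a, b].update(rho=1.0, p=0.0, sign="positive")
            net = _as_net(G)
            mine = node_metrics(net)
            g = network_metrics(net)
            ref = _brute_force_metrics(G)
            assert np.allclose(mine.degree, ref["degree"], atol=1e-8)
            assert np.allclose(mine.betweenness, ref["betweenness"], atol=1e-8)
            assert np.allclose(mine.closeness, ref["closeness"], atol=1e-8)
            assert np.allclose(mine.eigenvector, ref["eigenvector"], atol=1e-8)
            assert g.diameter == ref["diameter"]
            assert g.average_path_length == pytest.approx(ref["apl"], abs=1e-8)
            assert g.clustering_coefficient == pytest.approx(
                ref["clustering"], abs=1e-8
            )
            checked += 1


class TestPowerlawFit:
    def test_exact_powerlaw_r2_one(self):
        degrees = []
        for k in range(1, 11):
            degrees.extend([k] * int(round(10000 / k**2)))
        fit = powerlaw_fit_r2(degrees)
        assert fit.r_squared > 0.999
        assert fit.slope == pytest.approx(-2.0, abs=0.01)

    def test_flat_frequencies_reported_with_zero_slope(self):
        degrees = list(range(1, 11)) * 3
        fit = powerlaw_fit_r2(degrees)
        assert fit.r_squared == 1.0
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_r2_bounded(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            fit = powerlaw_fit_r2(rng.integers(1, 12, size=50))
            if not np.isnan(fit.r_squared):
                assert 0 <= fit.r_squared <= 1

    def test_too_few_distinct_degrees_undefined(self):
        assert np.isnan(powerlaw_fit_r2([1, 1, 2, 2]).r_squared)


class TestErdosRenyiBaseline:
    def test_edge_count_exact_and_deterministic(self):
        a = erdos_renyi_baseline(30, 60, reps=5, seed=3)
        b = erdos_renyi_baseline(30, 60, reps=5, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_clustering_matches_er_expectation(self):
        res = erdos_renyi_baseline(100, 500, reps=200, seed=4)
        cc = res.set_index("metric").loc["clustering_coefficient"]
        expected = 500 / (100 * 99 / 2)
        assert abs(cc["mean"] - expected) < 3 * cc["sd"] / np.sqrt(200) + 0.005


class TestNaturalConnectivity:
    def test_edgeless_graph_zero(self):
        G = nx.empty_graph(7)
        assert natural_connectivity(G) == 0.0

    def test_triangle_closed_form(self):
        # eigenvalues {2, -1, -1}
        net = _graph([("a", "b"), ("b", "c"), ("a", "c")])
        expected = np.log((np.exp(2) + 2 * np.exp(-1)) / 3)
        assert natural_connectivity(net) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.9963, abs=1e-4)

    def test_star_closed_form(self):
        # K_{1,3}: eigenvalues {+-sqrt(3), 0, 0}
        net = _graph([("h", "a"), ("h", "b"), ("h", "c")])
        s3 = np.sqrt(3)
        expected = np.log((np.exp(s3) + np.exp(-s3) + 2) / 4)
        assert natural_connectivity(net) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.6716, abs=1e-4)

    def test_monotone_under_edge_removal(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            G = nx.gnp_random_graph(10, 0.4, seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            before = natural_connectivity(G)
            edges = list(G.edges)
            G.remove_edge(*edges[rng.integers(len(edges))])
            assert natural_connectivity(G) <= before + 1e-12


class TestRobustness:
    def test_curve_starts_at_intact_value(self):
        net = _graph([(a, b) for a in range(6) for b in range(6) if a < b])
        curve = robustness_curve(net, strategy="random", max_fraction=0.5,
                                 steps=5, reps=10, seed=1)
        assert curve.mean[0] == pytest.approx(natural_connectivity(net))

    def test_complete_graph_one_removed_closed_form(self):
        net = _graph([(a, b) for a in range(10) for b in range(10) if a < b])
        curve = robustness_curve(net, strategy="degree_descending",
                                 max_fraction=0.1, steps=2, reps=1, seed=0)
        # K9: eigenvalues {8, -1 x8}
        expected = np.log((np.exp(8) + 8 * np.exp(-1)) / 9)
        assert curve.mean[1] == pytest.approx(expected, abs=1e-9)

    def test_random_strategy_seed_deterministic(self):
        net = _graph([(a, b) for a in range(8) for b in range(8) if a < b - 2])
        c1 = robustness_curve(net, seed=5, reps=8, steps=4)
        c2 = robustness_curve(net, seed=5, reps=8, steps=4)
        assert np.array_equal(c1.mean, c2.mean)

    def test_max_fraction_validated(self):
        net = _graph([("a", "b")])
        with pytest.raises(ValidationError):
            robustness_curve(net, max_fraction=1.0)


class TestModularity:
    def test_two_cliques_recovered(self):
        edges = [(f"a{i}", f"a{j}") for i in range(5) for j in range(5) if i < j]
        edges += [(f"b{i}", f"b{j}") for i in range(5) for j in range(5) if i < j]
        part, q = modularity_partition(_graph(edges), seed=1)
        assert q == pytest.approx(0.5)
        assert len({part[f"a{i}"] for i in range(5)}) == 1
        assert len({part[f"b{i}"] for i in range(5)}) == 1
        assert part["a0"] != part["b0"]

    def test_complete_graph_single_module(self):
        net = _graph([(a, b) for a in range(6) for b in range(6) if a < b])
        part, q = modularity_partition(net, seed=2)
        assert q == pytest.approx(0.0)
        assert len(set(part.values())) == 1

    def test_q_bounds_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for _ in range(10):
            G = nx.gnm_random_graph(15, 25, seed=int(rng.integers(2**31)))
            if G.number_of_edges() == 0:
                continue
            _, q = modularity_partition(_as_net(G), seed=3)
            assert -0.5 <= q <= 1.0

    def test_edgeless_rejected(self):
        with pytest.raises(ValidationError):
            modularity_partition(_as_net(nx.empty_graph(3)), seed=0)


class TestEdgeCensus:
    def _toy(self):
        G = nx.Graph()
        G.add_edge("A1", "A2", rho=0.9, p=0.0, sign="positive")
        G.add_edge("A1", "B1", rho=-0.9, p=0.0, sign="negative")
        G.add_edge("B1", "B2", rho=0.9, p=0.0, sign="positive")
        return _as_net(G)

    def test_hand_counts(self):
        labels = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        census = edge_census(self._toy(), labels).set_index(["label_a", "label_b"])
        assert tuple(census.loc[("A", "A")]) == (1, 0)
        assert tuple(census.loc[("B", "B")]) == (1, 0)
        assert tuple(census.loc[("A", "B")]) == (0, 1)

    def test_cell_sum_equals_edge_count(self):
        rng = np.random.default_rng(11)
        G = nx.gnm_random_graph(12, 20, seed=1)
        for a, b in G.edges:
            G.edges[a, b].update(
                rho=1.0, p=0.0,
                sign="positive" if rng.random() < 0.5 else "negative",
            )
        net = _as_net(G)
        labels = {n: rng.choice(["x", "y", "z"]) for n in G.nodes}
        census = edge_census(net, labels)
        assert (census.positive + census.negative).sum() == G.number_of_edges()

    def test_single_label_all_intra(self):
        census = edge_census(self._toy(), {n: "only" for n in "ABAB12"} |
                             {"A1": "only", "A2": "only", "B1": "only", "B2": "only"})
        assert len(census) == 1
        assert census.iloc[0].positive + census.iloc[0].negative == 3
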