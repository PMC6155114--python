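import itertools

import networkx as nx
import numpy as np
import pytest

import metagenet as mg
from metagenet.correlation import CorrelationResult
from metagenet.data_model import Prevalence, PrevalenceClass


def corr_from_matrices(genes, rho, q):
    rho = np.asarray(rho, dtype=float)
    q = np.asarray(q, dtype=float)
    return CorrelationResult(genes=list(genes), rho=rho, p=q.copy(), q=q,
                             deconvolved_rho=rho.copy())


def prev_map(**kwargs):
    out = {}
    for gene, label in kwargs.items():
        out[gene] = PrevalenceClass(Prevalence(label), 0)
    return out


class TestBuildNetwork:
    def test_edge_rule_positive(self):
        corr = corr_from_matrices(["a", "b"], [[1, 0.9], [0.9, 1]], [[0, 0.001], [0.001, 0]])
        net = mg.build_network(corr, threshold=0.818)
        assert net.has_edge("a", "b")
        assert net.edges["a", "b"]["sign"] == "+"

    def test_q_gate_blocks_edge(self):
        corr = corr_from_matrices(["a", "b"], [[1, 0.9], [0.9, 1]], [[0, 0.2], [0.2, 0]])
        net = mg.build_network(corr, threshold=0.818)
        assert net.number_of_edges() == 0

    def test_negative_sign(self):
        corr = corr_from_matrices(["a", "b"], [[1, -0.95], [-0.95, 1]],
                                  [[0, 0.001], [0.001, 0]])
        net = mg.build_network(corr, threshold=0.818)
        assert net.edges["a", "b"]["sign"] == "-"

    def test_isolated_genes_excluded(self):
        rho = np.eye(3)
        rho[0, 1] = rho[1, 0] = 0.9
        q = np.full((3, 3), 0.001)
        net = mg.build_network(corr_from_matrices(["a", "b", "c"], rho, q), threshold=0.5)
        assert set(net.nodes) == {"a", "b"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        rho = rng.uniform(-1, 1, (12, 12))
        rho = (rho + rho.T) / 2
        np.fill_diagonal(rho, 1.0)
        q = np.full_like(rho, 0.001)
        genes = [f"g{i}" for i in range(12)]
        prev_edges = None
        for thr in (0.2, 0.4, 0.6, 0.8):
            edges = set(map(frozenset, mg.build_network(
                corr_from_matrices(genes, rho, q), threshold=thr).edges))
            if prev_edges is not None:
                assert edges <= prev_edges
            prev_edges = edges

    def test_invalid_threshold(self):
        corr = corr_from_matrices(["a", "b"], np.eye(2), np.zeros((2, 2)))
        with pytest.raises(ValueError):
            mg.build_network(corr, threshold=1.5)


class TestSubnetworkPartition:
    def _triangle(self):
        corr = corr_from_matrices(
            ["a", "b", "c"],
            [[1, 0.9, 0.9], [0.9, 1, 0.9], [0.9, 0.9, 1]],
            np.full((3, 3), 1e-4),
        )
        return mg.build_network(
            corr, threshold=0.5,
            prevalence=prev_map(a="core", b="core", c="noncore"),
        )

    def test_all_core_subnetwork_is_whole(self):
        corr = corr_from_matrices(["a", "b"], [[1, 0.9], [0.9, 1]], np.full((2, 2), 1e-4))
        net = mg.build_network(corr, threshold=0.5, prevalence=prev_map(a="core", b="core"))
        sub = mg.subnetwork(net, "core")
        assert set(sub.edges) == set(net.edges)

    def test_bridge_edge_drops_from_class_subnetworks(self):
        corr = corr_from_matrices(["a", "b"], [[1, 0.9], [0.9, 1]], np.full((2, 2), 1e-4))
        net = mg.build_network(corr, threshold=0.5, prevalence=prev_map(a="core", b="noncore"))
        assert mg.subnetwork(net, "core").number_of_edges() == 0
        assert mg.subnetwork(net, "noncore").number_of_edges() == 0

    def test_triangle_partition(self):
        counts = mg.edge_partition(self._triangle())
        assert counts == {"core-core": 1, "noncore-noncore": 0, "core-noncore": 2}

    def test_partition_conserves_total(self, small_network):
        counts = mg.edge_partition(small_network)
        assert sum(counts.values()) == small_network.number_of_edges()
        core = mg.subnetwork(small_network, "core").number_of_edges()
        noncore = mg.subnetwork(small_network, "noncore").number_of_edges()
        assert core == counts["core-core"] and noncore == counts["noncore-noncore"]

    def test_unknown_class(self, small_network):
        with pytest.raises(ValueError):
            mg.subnetwork(small_network, "rare")


class TestTopology:
    def test_triangle(self):
        g = nx.complete_graph(3)
        nx.set_edge_attributes(g, "+", "sign")
        t = mg.topology_summary(g)
        assert (t.density, t.clustering_mean_local, t.diameter_lcc) == (1.0, 1.0, 1)

    def test_path_of_four(self):
        g = nx.path_graph(4)
        nx.set_edge_attributes(g, "+", "sign")
        t = mg.topology_summary(g)
        assert t.clustering_mean_local == 0.0 and t.diameter_lcc == 3

    def test_diameter_matches_bfs_oracle(self):
        g = nx.gnm_random_graph(40, 90, seed=5)
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        nx.set_edge_attributes(g, "+", "sign")
        oracle = max(
            max(lengths.values())
            for _, lengths in nx.all_pairs_shortest_path_length(g)
        )
        assert mg.topology_summary(g).diameter_lcc == oracle

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            mg.topology_summary(nx.Graph())


class TestPowerLaw:
    def test_exact_power_law_r2_one(self):
        degrees = []
        for k in range(1, 21):
            degrees += [k] * (10000 // k**2)
        r2, slope = mg.powerlaw_r2(degrees)
        assert r2 > 0.999
        assert slope == pytest.approx(-2.0, abs=0.05)

    def test_uniform_degrees_rejected(self):
        with pytest.raises(ValueError):
            mg.powerlaw_r2([4] * 50)

    def test_geometric_frequencies_curved(self):
        degrees = []
        for k in range(1, 21):
            degrees += [k] * max(1, int(2**20 * 2.0**-k))
        r2, _ = mg.powerlaw_r2(degrees)
        assert r2 < 0.95


class TestErNull:
    def test_max_edges_is_complete_graph(self):
        g, hist = mg.er_null(5, 10, seed=0)
        assert nx.is_isomorphic(g, nx.complete_graph(5))
        assert hist == {4: 5}

    def test_mean_degree_exact(self):
        g, _ = mg.er_null(30, 60, seed=1)
        assert sum(d for _, d in g.degree()) == 2 * 60

    def test_infeasible_m(self):
        with pytest.raises(ValueError):
            mg.er_null(4, 7)

    def test_degree_distribution_near_binomial(self):
        n, m = 40, 80
        p_edge = m / (n * (n - 1) / 2)
        counts = {}
        for seed in range(200):
            _, hist = mg.er_null(n, m, seed=seed)
            for k, c in hist.items():
                counts[k] = counts.get(k, 0) + c
        total = sum(counts.values())
        from scipy.stats import binom
        mean_emp = sum(k * c for k, c in counts.items()) / total
        assert mean_emp == pytest.approx(binom.mean(n - 1, p_edge), rel=0.05)


class TestNegativeEdges:
    def test_no_negative_edges(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+")
        s = mg.negative_edge_summary(g)
        assert s.endpoint_class_counts == {"n-n": 0, "n-e": 0, "e-e": 0}
        assert len(s.negative_degree) == 0

    def test_single_core_noncore_negative_edge(self):
        g = nx.Graph()
        g.add_node("a", prevalence="core")
        g.add_node("b", prevalence="noncore")
        g.add_edge("a", "b", sign="-")
        s = mg.negative_edge_summary(g)
        assert s.endpoint_class_counts == {"n-n": 0, "n-e": 1, "e-e": 0}
        assert s.negative_degree["a"] == 1 and s.negative_degree["b"] == 1

    def test_planted_anticorrelation_concentrates(self):
        spec = mg.SyntheticSpec(
            n_clusters=4, genes_per_cluster=20, n_background_genes=20,
            n_excluded_genes=0, frac_core=0.6, negative_pairs=((0, 1),), seed=13,
        )
        ds = mg.generate_dataset(spec)
        corr = mg.spearman_matrix(ds.abundance)
        net = mg.build_network(corr, threshold=0.55, matrix="rho",
                               prevalence=mg.classify_prevalence(ds.abundance),
                               metadata=ds.metadata)
        s = mg.negative_edge_summary(net)
        assert s.subgraph.number_of_edges() > 0
        bridging = sum(
            1 for a, b in s.subgraph.edges
            if {ds.truth.gene_cluster[a], ds.truth.gene_cluster[b]} == {0, 1}
        )
        assert bridging / s.subgraph.number_of_edges() >= 0.9


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank splits; 2 are as extreme -> p = 1/3
        _, p = mg.wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_samples_p_one(self):
        _, p = mg.wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert p == 1.0

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(8)
        x = rng.normal(3, 1, 50)
        y = rng.normal(0, 1, 50)
        _, p = mg.wilcoxon_rank_sum(x, y)
        assert p < 0.001

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mg.wilcoxon_rank_sum([], [1.0])
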