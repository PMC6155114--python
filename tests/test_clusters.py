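import networkx as nx
import numpy as np
import pytest

import metagenet as mg
from metagenet.clusters import membership_frame
from metagenet.simulate import nested_partition_graph


def signed(g):
    nx.set_edge_attributes(g, "+", "sign")
    return g


def two_cliques_with_bridge(k=5):
    g = nx.Graph()
    left = [f"L{i}" for i in range(k)]
    right = [f"R{i}" for i in range(k)]
    for side in (left, right):
        for i in range(k):
            for j in range(i + 1, k):
                g.add_edge(side[i], side[j], sign="+")
    g.add_edge(left[0], right[0], sign="+")
    return g, left, right


class TestDetectClusters:
    def test_two_cliques_split(self):
        g, left, right = two_cliques_with_bridge()
        cl = mg.detect_clusters(g, resolution=1.0, seed=0)
        groups = {}
        for v, c in cl.membership.items():
            groups.setdefault(c, set()).add(v)
        assert set(map(frozenset, groups.values())) == {frozenset(left), frozenset(right)}

    def test_complete_graph_single_cluster(self):
        cl = mg.detect_clusters(signed(nx.complete_graph(12)), seed=0)
        assert cl.n_clusters == 1

    def test_planted_partition_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        for seed in range(3):
            g = signed(nx.Graph(nx.planted_partition_graph(4, 25, 0.5, 0.02, seed=seed)))
            cl = mg.detect_clusters(g, seed=seed)
            nodes = sorted(g.nodes)
            ari = adjusted_rand_score([v // 25 for v in nodes],
                                      [cl.membership[v] for v in nodes])
            assert ari >= 0.9

    def test_membership_is_partition(self, small_network):
        cl = mg.detect_clusters(small_network, seed=1)
        assert set(cl.membership) == set(small_network.nodes)

    def test_negative_edges_ignored_for_modularity(self):
        g = nx.Graph()
        g.add_edge("a", "b", sign="+")
        g.add_edge("c", "d", sign="+")
        g.add_edge("b", "c", sign="-")
        cl = mg.detect_clusters(g, seed=0)
        assert cl.membership["a"] == cl.membership["b"]
        assert cl.membership["b"] != cl.membership["c"]

    def test_empty_and_bad_resolution(self):
        with pytest.raises(ValueError):
            mg.detect_clusters(nx.Graph())
        with pytest.raises(ValueError):
            mg.detect_clusters(signed(nx.complete_graph(3)), resolution=0.0)


class TestDominant:
    def _clustering(self, sizes):
        membership = {}
        node = 0
        for cid, size in enumerate(sizes):
            for _ in range(size):
                membership[f"v{node}"] = cid
                node += 1
        return mg.Clustering(1.0, membership, 0.0, 0)

    def test_min_size_rule(self):
        dom, loose = mg.dominant_clusters(self._clustering([50, 12, 3]), min_size=10)
        assert dom == [0, 1] and len(loose) == 3

    def test_min_size_one_keeps_all(self):
        dom, loose = mg.dominant_clusters(self._clustering([5, 1]), min_size=1)
        assert dom == [0, 1] and loose == set()

    def test_partition_total(self):
        cl = self._clustering([20, 9, 4, 1])
        dom, loose = mg.dominant_clusters(cl, min_size=10)
        dominant_nodes = sum(1 for c in cl.membership.values() if c in set(dom))
        assert dominant_nodes + len(loose) == len(cl.membership)


class TestMultiresHierarchy:
    def test_single_clique_stable_across_resolutions(self):
        g = signed(nx.complete_graph(8))
        cls = mg.multires_scan(g, resolutions=range(1, 6), seed=0)
        assert len(cls) == 5
        assert all(c.n_clusters == 1 for c in cls)

    def test_identical_levels_no_merges(self):
        g, *_ = two_cliques_with_bridge()
        cl = mg.detect_clusters(g, seed=0)
        h = mg.build_hierarchy([cl, mg.Clustering(2.0, dict(cl.membership), 0.0, 0)])
        assert h.merges == []
        assert all(c == p for (_, c), p in h.parent_links.items())

    def test_nested_graph_yields_planted_merges(self):
        g, sib_of, _ = nested_partition_graph(seed=5)
        cls = mg.multires_scan(g, range(1, 16), seed=5)
        h = mg.build_hierarchy(cls)
        assert cls[0].n_clusters == 4
        assert len(h.merges) == 2
        merged_pairs = set()
        for event in h.merges:
            level = h.resolutions.index(event.child_resolution)
            members = [v for v, c in cls[level].membership.items() if c in event.children]
            merged_pairs.add(tuple(sorted({sib_of[v] for v in members})))
        assert merged_pairs == {(0, 1), (2, 3)}

    def test_every_child_has_one_parent(self):
        g, *_ = nested_partition_graph(seed=6)
        cls = mg.multires_scan(g, range(1, 6), seed=6)
        h = mg.build_hierarchy(cls)
        for t, cl in enumerate(cls[:-1]):
            for c in set(cl.membership.values()):
                assert (t, c) in h.parent_links

    def test_resolutions_must_ascend(self):
        with pytest.raises(ValueError):
            mg.multires_scan(signed(nx.complete_graph(4)), resolutions=[2, 1])

    def test_hierarchy_exports(self, tmp_path):
        g, *_ = nested_partition_graph(seed=7)
        cls = mg.multires_scan(g, range(1, 16), seed=7)
        h = mg.build_hierarchy(cls)
        payload = h.to_json(tmp_path / "h.json")
        assert (tmp_path / "h.json").exists()
        assert len(payload["merges"]) == len(h.merges)
        text = h.to_text()
        assert "R=15" in text and "R=1 " in text


class TestConnectivityRoles:
    def test_two_cliques_connectivity_matrix(self):
        g, left, right = two_cliques_with_bridge()
        cl = mg.detect_clusters(g, seed=0)
        m = mg.inter_cluster_connectivity(g, cl)
        assert sorted(np.diag(m.values)) == [10, 10]
        off = m.values[~np.eye(2, dtype=bool)]
        assert (off == 1).all()

    def test_connectivity_conserves_edges(self, small_network):
        cl = mg.detect_clusters(small_network, seed=2)
        m = mg.inter_cluster_connectivity(small_network, cl).values
        total = np.triu(m).sum()
        assert total == small_network.number_of_edges()

    def test_roles_and_handshake(self):
        g, left, right = two_cliques_with_bridge()
        cl = mg.detect_clusters(g, seed=0)
        roles = mg.node_roles(g, cl)
        assert roles["L1"].role == "intra" and roles["L1"].between_degree == 0
        assert roles["L0"].role == "inter" and roles["L0"].between_degree == 1
        for v, r in roles.items():
            assert r.within_degree + r.between_degree == g.degree(v)
        within = sum(1 for a, b in g.edges if cl.membership[a] == cl.membership[b])
        assert sum(r.within_degree for r in roles.values()) == 2 * within
        assert sum(r.between_degree for r in roles.values()) == 2 * (g.number_of_edges() - within)


class TestHubs:
    def test_star_center_is_hub(self):
        g = signed(nx.star_graph(6))
        cl = mg.Clustering(1.0, {v: 0 for v in g.nodes}, 0.0, 0)
        hubs, table = mg.cluster_hubs(g, cl, [0])
        assert hubs[0] == 0
        assert table.loc[0, "degree"] == 6

    def test_one_hub_per_dominant_cluster(self, small_network):
        cl = mg.detect_clusters(small_network, seed=3)
        dom, _ = mg.dominant_clusters(cl, min_size=10)
        hubs, table = mg.cluster_hubs(small_network, cl, dom)
        assert sorted(hubs) == dom
        assert len(table) == len(dom)

    def test_planted_hub_recovered(self, small_dataset, small_network):
        cl = mg.detect_clusters(small_network, seed=4)
        dom, _ = mg.dominant_clusters(cl, min_size=10)
        hubs, _ = mg.cluster_hubs(small_network, cl, dom)
        planted = set(small_dataset.truth.hubs.values())
        recovered = sum(1 for h in hubs.values() if h in planted)
        assert recovered / len(hubs) >= 0.75

    def test_tie_break_lexicographic(self):
        g = nx.Graph()
        g.add_edge("b", "a", sign="+")
        g.add_edge("b", "c", sign="+")
        g.add_edge("a", "c", sign="+")  # all degree 2 -> lexicographic winner
        cl = mg.Clustering(1.0, {"a": 0, "b": 0, "c": 0}, 0.0, 0)
        hubs, _ = mg.cluster_hubs(g, cl, [0])
        assert hubs[0] == "a"

    def test_empty_dominant_set_rejected(self, small_network):
        cl = mg.detect_clusters(small_network, seed=5)
        with pytest.raises(ValueError):
            mg.cluster_hubs(small_network, cl, [])


def test_membership_frame_long_format(small_network):
    cls = mg.multires_scan(small_network, range(1, 4), seed=0)
    df = membership_frame(cls)
    assert set(df.columns) == {"gene", "resolution", "cluster"}
    assert len(df) == 3 * small_network.number_of_nodes()
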