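"""Expression-signature networks: merging, graphs, neighborhoods, enrichment."""

import math

import numpy as np
import pytest

from bitsig import (
    ComparisonResult,
    EdgeTable,
    build_graph,
    compare_self,
    merge_up_down,
    overlap_enrichment,
    pack,
    second_order_similarity,
    subnetwork,
)


def self_result(counts, ids=None, K=100):
    counts = np.triu(np.asarray(counts, dtype=np.uint32), k=1)
    n = counts.shape[0]
    ids = ids or [f"n{i}" for i in range(n)]
    return ComparisonResult(ids, ids, counts, "AND", K, is_self=True)


class TestMergeUpDown:
    def test_zeros(self):
        z = self_result(np.zeros((3, 3)))
        assert not merge_up_down(z, z).counts.any()

    def test_additive(self):
        up = self_result([[0, 3, 0], [0, 0, 0], [0, 0, 0]])
        down = self_result([[0, 4, 1], [0, 0, 0], [0, 0, 0]])
        merged = merge_up_down(up, down)
        assert merged.counts[0, 1] == 7 and merged.counts[0, 2] == 1

    def test_commutes(self, rng):
        a = self_result(rng.integers(0, 50, size=(6, 6)))
        b = self_result(rng.integers(0, 50, size=(6, 6)))
        assert (merge_up_down(a, b).counts == merge_up_down(b, a).counts).all()

    def test_random_elementwise_sum(self, rng):
        up = self_result(rng.integers(0, 99, size=(8, 8)))
        down = self_result(rng.integers(0, 99, size=(8, 8)))
        expect = up.counts.astype(int) + down.counts.astype(int)
        assert (merge_up_down(up, down).counts == expect).all()

    def test_rejects_non_and(self, rng):
        a = self_result(rng.integers(0, 9, size=(3, 3)))
        b = ComparisonResult(a.query_ids, a.library_ids, a.counts, "XOR", 100, is_self=True)
        with pytest.raises(ValueError, match="expected AND"):
            merge_up_down(a, b)

    def test_rejects_id_mismatch(self, rng):
        a = self_result(rng.integers(0, 9, size=(3, 3)))
        b = self_result(rng.integers(0, 9, size=(3, 3)), ids=["x", "y", "z"])
        with pytest.raises(ValueError, match="different signatures"):
            merge_up_down(a, b)


class TestBuildGraph:
    def test_top_k_larger_than_nonzero_pairs(self):
        merged = self_result([[0, 5, 0], [0, 0, 2], [0, 0, 0]])
        g = build_graph(merged, top_k=100)
        assert sorted(w for _, _, w in g.edges) == [2, 5]

    def test_top_1_is_maximum(self, rng):
        merged = self_result(rng.integers(0, 1000, size=(10, 10)))
        g = build_graph(merged, top_k=1)
        assert g.edges[0][2] == np.triu(merged.counts, 1).max()

    def test_top_k_matches_full_sort_with_tiebreak(self, rng):
        counts = rng.integers(0, 8, size=(20, 20))  # many ties
        merged = self_result(counts)
        g = build_graph(merged, top_k=15)
        iu = np.triu_indices(20, 1)
        rows = [(int(i), int(j), int(merged.counts[i, j]))
                for i, j in zip(*iu) if merged.counts[i, j] > 0]
        rows.sort(key=lambda r: (-r[2], r[0], r[1]))
        expect = [(f"n{i}", f"n{j}", w) for i, j, w in rows[:15]]
        assert g.edges == expect

    def test_threshold_mode(self, rng):
        merged = self_result(rng.integers(0, 30, size=(12, 12)))
        g = build_graph(merged, threshold=20)
        iu = np.triu_indices(12, 1)
        expect = int((merged.counts[iu] >= 20).sum())
        assert len(g) == expect
        assert all(w >= 20 for _, _, w in g.edges)

    def test_top_k_subset_of_threshold_at_kth_weight(self, rng):
        merged = self_result(rng.integers(0, 100, size=(15, 15)))
        g_top = build_graph(merged, top_k=10)
        kth = min(w for _, _, w in g_top.edges)
        g_thr = build_graph(merged, threshold=kth)
        thr_pairs = {frozenset((i, j)) for i, j, _ in g_thr.edges}
        assert all(frozenset((i, j)) in thr_pairs for i, j, _ in g_top.edges)

    def test_argument_validation(self, rng):
        merged = self_result(rng.integers(0, 9, size=(4, 4)))
        with pytest.raises(ValueError, match="exactly one"):
            build_graph(merged)
        with pytest.raises(ValueError, match="top_k"):
            build_graph(merged, top_k=0)
        with pytest.raises(ValueError, match="threshold"):
            build_graph(merged, threshold=-1)

    def test_rejects_cross_comparison(self, rng):
        res = ComparisonResult(["a"], ["b", "c"],
                               rng.integers(0, 5, size=(1, 2)).astype(np.uint32),
                               "AND", 10)
        with pytest.raises(ValueError, match="self-comparison"):
            build_graph(res, top_k=1)


def edge_table(edges):
    return EdgeTable(edges=[(f"n{i}", f"n{j}", w) for i, j, w in edges])


class TestSubnetwork:
    def test_all_nodes_as_seeds_keeps_graph(self, rng):
        g = edge_table([(0, 1, 5), (1, 2, 3), (3, 4, 2)])
        sub = subnetwork(g, set(g.nodes()))
        assert sub.edges == g.edges

    def test_star_from_center(self):
        g = edge_table([(0, k, 1) for k in range(1, 6)])
        sub = subnetwork(g, {"n0"})
        assert len(sub) == 5

    def test_one_hop_closure_oracle(self, rng):
        n = 25
        edges = []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.15:
                    edges.append((i, j, int(rng.integers(1, 50))))
        g = edge_table(edges)
        seeds = {"n1", "n4", "n7"}
        sub = subnetwork(g, seeds)
        # brute-force: nodes adjacent to a seed, plus the seeds
        keep = set(seeds)
        for i, j, _ in g.edges:
            if i in seeds:
                keep.add(j)
            if j in seeds:
                keep.add(i)
        expect = [(i, j, w) for i, j, w in g.edges if i in keep and j in keep]
        assert sub.edges == expect

    def test_top_edges_trim(self):
        g = edge_table([(0, 1, 9), (0, 2, 5), (0, 3, 7)])
        sub = subnetwork(g, {"n0"}, top_edges=2)
        assert [w for _, _, w in sub.edges] == [9, 7]

    def test_missing_seeds_rejected(self):
        g = edge_table([(0, 1, 1)])
        with pytest.raises(ValueError, match="zz"):
            subnetwork(g, {"zz"})
        with pytest.raises(ValueError, match="empty"):
            subnetwork(g, set())


class TestSecondOrderSimilarity:
    def test_triangle_every_pair_shares_one(self):
        g = edge_table([(0, 1, 30), (1, 2, 30), (0, 2, 30)])
        res = second_order_similarity(g, edge_cut=20)
        iu = np.triu_indices(3, 1)
        assert (res.counts[iu] == 1).all()

    def test_star_leaves_share_center(self):
        g = edge_table([(0, k, 99) for k in range(1, 5)])
        res = second_order_similarity(g, edge_cut=20)
        idx = {n: k for k, n in enumerate(res.query_ids)}
        sym = res.symmetric_counts()
        for a in range(1, 5):
            for b in range(a + 1, 5):
                assert sym[idx[f"n{a}"], idx[f"n{b}"]] == 1
            assert sym[idx["n0"], idx[f"n{a}"]] == 0

    def test_common_neighbor_oracle(self, rng):
        n = 30
        edges = [(i, j, int(rng.integers(1, 60)))
                 for i in range(n) for j in range(i + 1, n) if rng.random() < 0.2]
        g = edge_table(edges)
        cut = 25
        res = second_order_similarity(g, edge_cut=cut)
        nbrs = {node: set() for node in g.nodes()}
        for i, j, w in g.edges:
            if w >= cut:
                nbrs[i].add(j)
                nbrs[j].add(i)
        idx = {n_: k for k, n_ in enumerate(res.query_ids)}
        sym = res.symmetric_counts()
        for a in g.nodes():
            for b in g.nodes():
                if a != b:
                    assert sym[idx[a], idx[b]] == len(nbrs[a] & nbrs[b])

    def test_depends_only_on_binarized_adjacency(self, rng):
        edges = [(0, 1, 25), (1, 2, 40), (0, 3, 30), (2, 3, 21)]
        g1 = edge_table(edges)
        g2 = edge_table([(i, j, w * 10) for i, j, w in edges])
        a = second_order_similarity(g1, edge_cut=20).counts
        b = second_order_similarity(g2, edge_cut=20).counts
        assert (a == b).all()

    def test_empty_after_cut_rejected(self):
        g = edge_table([(0, 1, 3)])
        with pytest.raises(ValueError, match="survive"):
            second_order_similarity(g, edge_cut=20)


def hypergeom_tail(U, n_set, n_sig, x):
    """P(overlap >= x) by explicit combinatorial summation."""
    total = math.comb(U, n_sig)
    return sum(
        math.comb(n_set, k) * math.comb(U - n_set, n_sig - k)
        for k in range(x, min(n_set, n_sig) + 1)
    ) / total


class TestOverlapEnrichment:
    def test_zero_overlap_gives_one(self):
        assert overlap_enrichment({"a"}, {"b"}, 100) == 1.0

    def test_degenerate_full_universe(self):
        u = {f"g{k}" for k in range(10)}
        assert overlap_enrichment(u, u, 10) == pytest.approx(1.0)

    def test_worked_example(self, rng):
        universe = [f"g{k}" for k in range(100)]
        sig = set(universe[:5]) | set(universe[20:25])          # 10 features
        gs = set(universe[:5]) | set(universe[50:60])           # 15, overlap 5
        got = overlap_enrichment(sig, gs, 100)
        assert got == pytest.approx(hypergeom_tail(100, 15, 10, 5), abs=1e-12)

    def test_random_against_combinatorial_sum(self, rng):
        for _ in range(50):
            U = int(rng.integers(20, 201))
            n_sig = int(rng.integers(1, U // 2))
            n_set = int(rng.integers(1, U // 2))
            sig = set(rng.choice(U, size=n_sig, replace=False).tolist())
            gs = set(rng.choice(U, size=n_set, replace=False).tolist())
            overlap = len(sig & gs)
            got = overlap_enrichment(sig, gs, U)
            assert abs(got - hypergeom_tail(U, n_set, n_sig, overlap)) < 1e-12

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            overlap_enrichment({1, 2, 3}, {4, 5}, 4)


class TestEdgeTable:
    def test_rejects_self_loop_and_duplicates(self):
        with pytest.raises(ValueError, match="self-loop"):
            EdgeTable(edges=[("a", "a", 1)])
        with pytest.raises(ValueError, match="duplicate"):
            EdgeTable(edges=[("a", "b", 1), ("b", "a", 2)])

    def test_planted_cluster_recovery(self):
        """Connected components of the top-k graph recover planted clusters."""
        import networkx as nx
        from bitsig import lincs_like, merge_up_down

        down, up, truth = lincs_like(seed=7)
        merged = merge_up_down(
            compare_self(up, "AND"), compare_self(down, "AND")
        )
        n_within = sum(
            1 for i in range(len(truth)) for j in range(i + 1, len(truth))
            if truth[i] == truth[j]
        )
        g = build_graph(merged, top_k=n_within).to_networkx()
        g.add_nodes_from(up.signature_ids)
        pred = {}
        for c, comp in enumerate(nx.connected_components(g)):
            for node in comp:
                pred[node] = c
        labels = dict(zip(up.signature_ids, truth))
        # every planted cluster maps to exactly one component and vice versa
        for i, a in enumerate(up.signature_ids):
            for b in up.signature_ids[i + 1:]:
                same_truth = labels[a] == labels[b]
                same_pred = pred[a] == pred[b]
                assert same_truth == same_pred
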