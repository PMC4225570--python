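"""Clustering flavors, dendrogram structure, truncation and serialization."""
import numpy as np
import pytest

from specseg import hclust, simmap
from conftest import random_truncated_tree


class TestDistanceMatrix:
    def test_identical_rows_distance_zero(self):
        X = np.array([[0.1, 0.5, 0.9], [0.1, 0.5, 0.9]])
        for metric in ("correlation", "power"):
            d = hclust.distance_matrix(X, metric)
            assert d[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_rows_distance_two(self):
        X = np.array([[0.0, 0.5, 1.0], [1.0, 0.5, 0.0]])
        d = hclust.distance_matrix(X, "correlation")
        assert d[0, 1] == pytest.approx(2.0)

    def test_correlation_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        X = rng.random((8, 20))
        d = hclust.distance_matrix(X, "correlation")
        for i, j in [(0, 1), (2, 5), (3, 7), (4, 6), (1, 6)]:
            r = np.corrcoef(X[i], X[j])[0, 1]
            assert d[i, j] == pytest.approx(1 - r, abs=1e-12)

    def test_power_matches_scalar_formula(self):
        rng = np.random.default_rng(12)
        X = rng.random((6, 15))
        d = hclust.distance_matrix(X, "power", alpha=1.5)
        for i, j in [(0, 5), (1, 2)]:
            assert d[i, j] == pytest.approx(
                simmap.power_distance(X[i], X[j], 1.5), abs=1e-9)

    def test_zero_variance_row_named(self):
        X = np.array([[0.2, 0.2, 0.2], [0.1, 0.5, 0.9]])
        with pytest.raises(ValueError, match="row 0"):
            hclust.distance_matrix(X, "correlation")


def _naive_ward(dist):
    """Reference O(N^3) Ward agglomeration: the Lance-Williams update applied
    to squared dissimilarities (the Matlab/scipy convention), lowest-pair ties."""
    n = dist.shape[0]
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    Z = []
    nxt = n
    while len(active) > 1:
        (i, j) = min(d, key=lambda ij: (d[ij], ij))
        h = d[(i, j)]
        for k in sorted(active - {i, j}):
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            ni, nj, nk = size[i], size[j], size[k]
            new = np.sqrt(
                ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * h**2)
                / (ni + nj + nk)
            )
            d[(min(nxt, k), max(nxt, k))] = new
        for key in list(d):
            if i in key or j in key:
                del d[key]
        size[nxt] = size[i] + size[j]
        active -= {i, j}
        active.add(nxt)
        Z.append([i, j, h, size[nxt]])
        nxt += 1
    return np.array(Z)


class TestWardLinkage:
    def test_two_items_merge_at_given_distance(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        tree = hclust.ward_linkage(d)
        assert tree.n_leaves == 2
        assert tree.merge_height(tree.root) == pytest.approx(0.7)

    def test_three_equidistant_points_forced_topology(self):
        d = np.ones((3, 3)) - np.eye(3)
        tree = hclust.ward_linkage(d)
        assert tree.n_vertices == 5
        assert set(tree.leaves_under(tree.root).tolist()) == {0, 1, 2}

    def test_matches_independent_lance_williams_on_euclidean_toy_data(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(15, 3))
        from scipy.spatial.distance import pdist, squareform

        D = squareform(pdist(X))
        ours = hclust.ward_linkage(D)
        ref = _naive_ward(D)
        # same merge heights and same partition at every level
        np.testing.assert_allclose(np.sort(ours.Z[:, 2]), np.sort(ref[:, 2]),
                                   rtol=1e-8)
        for k in (2, 3, 5):
            a = hclust.horizontal_cut(ours, k)
            b = hclust.horizontal_cut(hclust.Dendrogram(ref), k)
            from specseg.validate import rand_index

            assert rand_index(a, b) == 1.0

    def test_nonfinite_rejected(self):
        d = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="non-finite"):
            hclust.ward_linkage(d)


class TestHorizontalCut:
    def test_extremes(self, four_leaf_tree):
        assert len(np.unique(hclust.horizontal_cut(four_leaf_tree, 1))) == 1
        assert len(np.unique(hclust.horizontal_cut(four_leaf_tree, 4))) == 4

    def test_two_clusters_of_balanced_tree(self, four_leaf_tree):
        labels = hclust.horizontal_cut(four_leaf_tree, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_out_of_range(self, four_leaf_tree):
        with pytest.raises(ValueError, match="out of range"):
            hclust.horizontal_cut(four_leaf_tree, 5)


class TestTruncateTopmost:
    def test_no_pruning_when_v_covers_tree(self, four_leaf_tree):
        t = hclust.truncate_topmost(four_leaf_tree, V=7)
        assert t.n_vertices == 7
        assert sorted(len(v) for v in t.frontier_items.values()) == [1, 1, 1, 1]

    def test_v1_frontier_is_root(self, four_leaf_tree):
        t = hclust.truncate_topmost(four_leaf_tree, V=1)
        assert t.frontier == [four_leaf_tree.root]
        np.testing.assert_array_equal(t.frontier_items[t.root], np.arange(4))

    def test_v3_keeps_root_and_children(self, four_leaf_tree):
        t = hclust.truncate_topmost(four_leaf_tree, V=3)
        assert t.n_vertices == 3
        assert sorted(t.frontier) == [4, 5]
        np.testing.assert_array_equal(t.frontier_items[4], [0, 1])
        np.testing.assert_array_equal(t.frontier_items[5], [2, 3])

    def test_items_conserved_at_any_v(self):
        rng = np.random.default_rng(14)
        d, _ = random_truncated_tree(rng, 20)
        for V in (1, 5, 9, 39):
            t = hclust.truncate_topmost(d, V)
            covered = np.concatenate(list(t.frontier_items.values()))
            assert sorted(covered.tolist()) == list(range(20))


class TestBisectingTwoMeans:
    def test_two_items_one_split(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        t = hclust.bisecting_two_means(X, vertex_budget=3, seed=0)
        assert t.n_vertices == 3
        assert sorted(len(v) for v in t.frontier_items.values()) == [1, 1]

    def test_first_split_recovers_separated_blobs(self):
        rng = np.random.default_rng(15)
        a = rng.normal(0, 0.05, size=(30, 4))
        b = rng.normal(3, 0.05, size=(20, 4))
        X = np.vstack([a, b])
        t = hclust.bisecting_two_means(X, vertex_budget=3, seed=1)
        parts = [set(v.tolist()) for v in t.frontier_items.values()]
        assert {frozenset(range(30)), frozenset(range(30, 50))} == {
            frozenset(p) for p in parts}

    def test_same_seed_identical_tree(self):
        rng = np.random.default_rng(16)
        X = rng.random((40, 6))
        t1 = hclust.bisecting_two_means(X, vertex_budget=15, seed=42)
        t2 = hclust.bisecting_two_means(X, vertex_budget=15, seed=42)
        assert t1.children_map == t2.children_map
        assert all(np.array_equal(t1.frontier_items[k], t2.frontier_items[k])
                   for k in t1.frontier_items)

    def test_splits_never_increase_within_cluster_sse(self):
        rng = np.random.default_rng(17)
        X = rng.random((60, 5))
        t = hclust.bisecting_two_means(X, vertex_budget=21, seed=2)
        for v, (a, b) in t.children_map.items():
            assert t.heights[a] + t.heights[b] <= t.heights[v] + 1e-9

    def test_budget_caps_vertex_count(self):
        rng = np.random.default_rng(18)
        X = rng.random((50, 4))
        t = hclust.bisecting_two_means(X, vertex_budget=9, seed=3)
        assert t.n_vertices <= 9


class TestSerialization:
    def test_linkage_csv_round_trip(self, tmp_path, four_leaf_tree):
        path = tmp_path / "link.csv"
        four_leaf_tree.to_linkage_csv(path)
        back = hclust.Dendrogram.from_linkage_csv(path)
        np.testing.assert_allclose(back.Z, four_leaf_tree.Z)

    def test_newick_round_trip_preserves_partitions(self):
        rng = np.random.default_rng(19)
        X = rng.normal(size=(12, 3))
        from scipy.spatial.distance import pdist, squareform

        d = hclust.ward_linkage(squareform(pdist(X)))
        back = hclust.Dendrogram.from_newick(d.to_newick())
        from specseg.validate import rand_index

        for k in (2, 4, 6):
            assert rand_index(hclust.horizontal_cut(d, k),
                              hclust.horizontal_cut(back, k)) == 1.0
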