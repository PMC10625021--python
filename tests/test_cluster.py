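import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score, silhouette_score

from trajcluster.cluster import (cut_tree, hamming_matrix, leaf_order,
                                 order_by_severity, silhouette,
                                 visualization_matrix, ward_cluster,
                                 ward_linkage)


def brute_force_hamming(seqs):
    k = len(seqs)
    D = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(k):
            D[i, j] = sum(int(a != b) for a, b in zip(seqs[i], seqs[j]))
    return D


def ward_oracle(points, weights):
    """From-scratch greedy Ward agglomeration on coordinates.

    Each step recomputes the increase in within-cluster sum of squares for
    every cluster pair from the raw points and merges the minimiser;
    heights follow the sqrt(2 * delta-ESS) convention, ties break on the
    smallest node-id pair.
    """
    points = np.asarray(points, dtype=float)
    weights = np.asarray(weights, dtype=float)
    K = len(points)
    clusters = {i: ([i], i) for i in range(K)}  # members, node id
    Z = []
    for step in range(K - 1):
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b:
                    continue
                ma, _ = clusters[a]
                mb, _ = clusters[b]
                wa, wb = weights[ma].sum(), weights[mb].sum()
                mu_a = (weights[ma, None] * points[ma]).sum(0) / wa
                mu_b = (weights[mb, None] * points[mb]).sum(0) / wb
                d_ess = wa * wb / (wa + wb) * ((mu_a - mu_b) ** 2).sum()
                ida, idb = clusters[a][1], clusters[b][1]
                key = (d_ess, min(ida, idb), max(ida, idb))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d_ess, ida, idb), a, b = best
        Z.append((ida, idb, np.sqrt(2 * d_ess),
                  weights[clusters[a][0]].sum() + weights[clusters[b][0]].sum()))
        clusters[a] = (clusters[a][0] + clusters[b][0], K + step)
        del clusters[b]
    return np.asarray(Z)


class TestHammingMatrix:
    def test_identical_pair_zero(self):
        s = np.ones((2, 12), dtype=int)
        assert (hamming_matrix(s) == 0).all()

    def test_complementary_binary_pair(self):
        s = np.array([[0] * 10, [1] * 10])
        D = hamming_matrix(s)
        assert D[0, 1] == 10 and D[1, 0] == 10

    def test_four_short_sequences_vs_nested_loops(self):
        seqs = np.array([[0, 1, 2, 0, 3, 1],
                         [0, 1, 0, 0, 3, 2],
                         [1, 1, 2, 2, 3, 1],
                         [0, 0, 0, 0, 0, 0]])
        assert (hamming_matrix(seqs) == brute_force_hamming(seqs)).all()

    def test_random_instances_vs_oracle(self, rng):
        for _ in range(5):
            k = int(rng.integers(2, 50))
            T = int(rng.integers(2, 50))
            seqs = rng.integers(0, 4, size=(k, T))
            assert (hamming_matrix(seqs) == brute_force_hamming(seqs)).all()

    def test_non_2d_rejected(self):
        with pytest.raises(ValueError):
            hamming_matrix(np.zeros(5))


class TestWardLinkage:
    def test_two_leaves_single_merge(self):
        D = np.array([[0.0, 3.0], [3.0, 0.0]])
        model = ward_cluster(D, n_clusters=1)
        assert model.merges.shape == (1, 4)
        assert (cut_tree(model.merges, 2, 1) == [1, 1]).all()
        assert (cut_tree(model.merges, 2, 2) == [1, 2]).all()

    def test_unit_weights_match_scipy(self, rng):
        X = rng.normal(size=(11, 3))
        Z_ours = ward_linkage(squareform(pdist(X)))
        Z_scipy = linkage(pdist(X), "ward")
        np.testing.assert_allclose(Z_ours, Z_scipy, atol=1e-8)

    def test_five_medoids_vs_quadratic_oracle(self, rng):
        X = rng.normal(size=(5, 2))
        Z = ward_linkage(squareform(pdist(X)), np.ones(5))
        Zo = ward_oracle(X, np.ones(5))
        np.testing.assert_allclose(Z, Zo, atol=1e-8)

    def test_weighted_vs_quadratic_oracle_k12(self, rng):
        for _ in range(3):
            K = 12
            X = rng.normal(size=(K, 3))
            w = rng.integers(1, 6, size=K).astype(float)
            Z = ward_linkage(squareform(pdist(X)), w)
            Zo = ward_oracle(X, w)
            np.testing.assert_allclose(Z, Zo, atol=1e-8)

    def test_weighted_equals_scipy_on_expanded_points(self, rng):
        Xu = rng.normal(size=(7, 2))
        w = rng.integers(1, 4, size=7)
        Ze = linkage(pdist(np.repeat(Xu, w, axis=0)), "ward")
        Zw = ward_linkage(squareform(pdist(Xu)), w)
        np.testing.assert_allclose(np.sort(Zw[:, 2]),
                                   np.sort(Ze[:, 2])[-(len(Xu) - 1):], atol=1e-8)

    def test_merge_heights_non_decreasing(self, rng):
        X = rng.normal(size=(20, 4))
        Z = ward_linkage(squareform(pdist(X)))
        assert (np.diff(Z[:, 2]) >= -1e-12).all()

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            ward_linkage(D)

    def test_two_separated_groups_recovered(self, rng):
        # inter-group distance >> intra-group: cut at 2 recovers the labels
        a = rng.integers(0, 2, size=(6, 40))
        b = rng.integers(2, 4, size=(6, 40))
        seqs = np.vstack([a, b])
        model = ward_cluster(hamming_matrix(seqs), n_clusters=2)
        truth = [0] * 6 + [1] * 6
        assert adjusted_rand_score(truth, model.labels) == 1.0


class TestSeverityOrdering:
    def _model(self, labels, counts=None):
        K = len(labels)
        Z = np.zeros((K - 1, 4))
        # only labels/counts matter for order_by_severity
        from trajcluster.cluster import ClusterModel
        return ClusterModel(merges=Z, n_leaves=K,
                            member_counts=np.ones(K, dtype=int) if counts is None
                            else np.asarray(counts),
                            n_clusters=int(np.max(labels)),
                            labels=np.asarray(labels), silhouette_value=None)

    def test_orders_by_mean_episode_count(self):
        # medoid 0 -> low severity, medoid 1 -> high; labels reversed on input
        T = 50
        s_low = np.zeros(T, dtype=int)
        s_high = np.zeros(T, dtype=int)
        s_high[[5, 7, 9, 20, 22, 30]] = 1  # several episodes
        seqs = np.vstack([s_high, s_high, s_low, s_low])
        assignment = np.array([0, 0, 1, 1])
        model = self._model([1, 2])  # high-severity medoid currently labelled 1
        out = order_by_severity(model, seqs, assignment)
        assert out.labels.tolist() == [2, 1]

    def test_tie_broken_by_hospitalised_days(self):
        T = 60
        short = np.zeros(T, dtype=int)
        short[:3] = 1  # 1 episode, 3 days
        long = np.zeros(T, dtype=int)
        long[:30] = 1  # 1 episode, 30 days
        seqs = np.vstack([long, short])
        assignment = np.array([0, 1])
        model = self._model([1, 2])
        out = order_by_severity(model, seqs, assignment)
        assert out.labels.tolist() == [2, 1]

    def test_already_ordered_is_identity(self):
        T = 40
        a = np.zeros(T, dtype=int)
        b = np.zeros(T, dtype=int)
        b[::4] = 1
        seqs = np.vstack([a, b])
        model = self._model([1, 2])
        out = order_by_severity(model, seqs, np.array([0, 1]))
        assert out.labels.tolist() == [1, 2]


class TestSilhouette:
    def test_two_collapsed_separated_clusters(self):
        D = np.array([[0, 0, 9, 9],
                      [0, 0, 9, 9],
                      [9, 9, 0, 0],
                      [9, 9, 0, 0]], dtype=float)
        assert silhouette(D, [1, 1, 2, 2]) == pytest.approx(1.0)

    def test_random_labels_near_zero(self, rng):
        vals = []
        for _ in range(50):
            X = rng.normal(size=(30, 5))
            D = squareform(pdist(X))
            labels = rng.integers(1, 3, size=30)
            if len(np.unique(labels)) < 2:
                continue
            vals.append(silhouette(D, labels))
        assert abs(np.mean(vals)) <= 0.1

    def test_six_point_hand_computation(self):
        # 1-D points: cluster A = {0, 1, 2}, cluster B = {10, 11, 14}
        pts = np.array([0.0, 1.0, 2.0, 10.0, 11.0, 14.0])
        D = np.abs(pts[:, None] - pts[None, :])
        labels = [1, 1, 1, 2, 2, 2]
        # hand computation, e.g. point 0: a = (1+2)/2 = 1.5,
        # b = (10+11+14)/3 = 35/3; s = (35/3-1.5)/(35/3)
        expected = []
        for i in range(6):
            own = [j for j in range(6) if labels[j] == labels[i] and j != i]
            oth = [j for j in range(6) if labels[j] != labels[i]]
            a = np.mean([D[i, j] for j in own])
            b = np.mean([D[i, j] for j in oth])
            expected.append((b - a) / max(a, b))
        assert silhouette(D, labels) == pytest.approx(np.mean(expected))

    def test_matches_sklearn_on_expanded_weights(self, rng):
        X = rng.normal(size=(8, 3))
        w = rng.integers(1, 4, size=8)
        labels = np.array([1, 1, 1, 1, 2, 2, 2, 2])
        D = squareform(pdist(X))
        ours = silhouette(D, labels, w)
        Xe = np.repeat(X, w, axis=0)
        le = np.repeat(labels, w)
        ref = silhouette_score(squareform(pdist(Xe)), le, metric="precomputed")
        assert ours == pytest.approx(ref, abs=1e-10)

    def test_single_cluster_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError):
            silhouette(D, [1, 1, 1])

    def test_singleton_only_rejected(self):
        D = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ValueError, match="singleton"):
            silhouette(D, [1, 2])


class TestVisualizationMatrix:
    def test_counts_and_conservation(self, small_medoids):
        from trajcluster.cluster import hamming_matrix as hm
        D = hm(small_medoids.medoids)
        model = ward_cluster(D, small_medoids.member_counts, 4)
        raster, row_clusters = visualization_matrix(model, small_medoids.medoids)
        assert raster.shape[0] == small_medoids.member_counts.sum()
        assert len(row_clusters) == raster.shape[0]

    def test_medoid_with_count_three_repeats(self):
        medoids = np.array([[0, 0, 0], [1, 1, 1]])
        D = hamming_matrix(medoids)
        model = ward_cluster(D, np.array([3, 2]), n_clusters=2)
        raster, rc = visualization_matrix(model, medoids)
        assert raster.shape == (5, 3)
        # three identical adjacent rows for the count-3 medoid
        runs = [len(list(g)) for _, g in itertools.groupby(map(tuple, raster))]
        assert sorted(runs) == [2, 3]

    def test_cluster_blocks_are_contiguous(self, small_medoids, small_sequences):
        _, seqs = small_sequences
        D = hamming_matrix(small_medoids.medoids)
        model = ward_cluster(D, small_medoids.member_counts, 4)
        model = order_by_severity(model, seqs, small_medoids.assignment)
        _, rc = visualization_matrix(model, small_medoids.medoids)
        changes = (np.diff(rc) != 0).sum()
        assert changes == model.n_clusters - 1


def test_leaf_order_is_permutation(small_medoids):
    D = hamming_matrix(small_medoids.medoids)
    model = ward_cluster(D, small_medoids.member_counts, 4)
    assert sorted(model.leaf_order.tolist()) == list(range(model.n_leaves))
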