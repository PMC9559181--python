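"""k-means, silhouettes, and silhouette-based selection of K."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import silhouette_samples

from migpattern import (
    EmbeddedPeriod,
    EmbeddingParams,
    ParameterError,
    cluster_all_periods,
    kmeans_cluster,
    select_k,
    silhouette_values,
)


def as_embedded(points, period=1):
    points = np.asarray(points, float)
    return EmbeddedPeriod(
        period, list(range(len(points))), points, "umap", EmbeddingParams(), 0
    )


def brute_silhouettes(points, labels):
    """Direct three-branch implementation from the definitions."""
    points = np.asarray(points, float)
    labels = np.asarray(labels)
    out = np.zeros(len(points))
    clusters = {k: np.nonzero(labels == k)[0] for k in np.unique(labels)}
    for i in range(len(points)):
        own = clusters[labels[i]]
        if len(own) == 1:
            out[i] = 0.0
            continue
        a = sum(math.dist(points[i], points[j]) for j in own if j != i) / (len(own) - 1)
        b = min(
            sum(math.dist(points[i], points[j]) for j in mem) / len(mem)
            for k, mem in clusters.items()
            if k != labels[i]
        )
        if a < b:
            out[i] = 1 - a / b
        elif a == b:
            out[i] = 0.0
        else:
            out[i] = b / a - 1
    return out


def brute_kmeans_optimum(points, K=2):
    """Global WCSS optimum by exhaustive enumeration of all K-partitions."""
    N = len(points)
    best = math.inf
    for assignment in itertools.product(range(K), repeat=N):
        if len(set(assignment)) < K:
            continue
        J = 0.0
        for k in range(K):
            members = points[np.array(assignment) == k]
            J += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, J)
    return best


class TestKmeans:
    def test_k_equals_n_gives_zero_wcss(self):
        rng = np.random.default_rng(0)
        e = as_embedded(rng.normal(size=(6, 2)))
        c = kmeans_cluster(e, 6, n_init=5, seed=0)
        assert c.wcss == pytest.approx(0.0, abs=1e-12)
        assert len(set(c.labels.tolist())) == 6

    def test_k_equals_one_gives_total_scatter(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(9, 2))
        c = kmeans_cluster(as_embedded(pts), 1, n_init=1, seed=0)
        expected = ((pts - pts.mean(axis=0)) ** 2).sum()
        assert c.wcss == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_instances_reach_global_optimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        pts = rng.normal(scale=5, size=(n, 2))
        c = kmeans_cluster(as_embedded(pts), 2, n_init=50, seed=seed)
        assert c.wcss == pytest.approx(brute_kmeans_optimum(pts, 2), rel=1e-9)

    def test_wcss_never_increases_within_a_run(self):
        rng = np.random.default_rng(3)
        e = as_embedded(rng.normal(size=(40, 2)))
        c = kmeans_cluster(e, 4, n_init=3, seed=1)
        hist = np.array(c.wcss_history)
        assert (np.diff(hist) <= 1e-9).all()

    def test_every_cluster_non_empty(self):
        # duplicated points force the empty-cluster repair path
        pts = np.array([[0.0, 0.0]] * 5 + [[10.0, 10.0]] * 5)
        c = kmeans_cluster(as_embedded(pts), 4, n_init=5, seed=0)
        assert set(c.labels.tolist()) == set(range(4))

    def test_k_out_of_range_rejected(self):
        e = as_embedded(np.zeros((4, 2)))
        with pytest.raises(ParameterError):
            kmeans_cluster(e, 5, seed=0)


class TestSilhouettes:
    def test_coincident_separated_clusters_score_one(self):
        pts = np.array([[0.0, 0.0]] * 3 + [[20.0, 0.0]] * 3)
        s, msc = silhouette_values(pts, [0, 0, 0, 1, 1, 1])
        np.testing.assert_array_equal(s, np.ones(6))
        assert msc == 1.0

    def test_equidistant_point_scores_zero(self):
        # middle point has a = b exactly by symmetry
        pts = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        s, _ = silhouette_values(pts, [0, 0, 1])
        assert s[1] == 0.0

    def test_singleton_cluster_scores_zero(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [10.0, 0.0]])
        s, _ = silhouette_values(pts, [0, 0, 1])
        assert s[2] == 0.0

    def test_fewer_than_two_clusters_rejected(self):
        with pytest.raises(ParameterError):
            silhouette_values(np.zeros((3, 2)), [0, 0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 31))
        k = int(rng.integers(2, 5))
        pts = rng.normal(scale=10, size=(n, 2))
        labels = rng.integers(0, k, size=n)
        if len(np.unique(labels)) < 2:
            labels[0] = (labels[1] + 1) % k
        s, msc = silhouette_values(pts, labels)
        np.testing.assert_allclose(s, brute_silhouettes(pts, labels), atol=1e-12)
        np.testing.assert_allclose(s, silhouette_samples(pts, labels), atol=1e-9)
        assert (s >= -1).all() and (s <= 1).all()
        assert -1 <= msc <= 1

    def test_precomputed_distance_variant_agrees(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(12, 2))
        labels = rng.integers(0, 3, size=12)
        labels[:3] = [0, 1, 2]
        from scipy.spatial.distance import cdist

        s1, m1 = silhouette_values(pts, labels)
        s2, m2 = silhouette_values(cdist(pts, pts), labels, precomputed=True)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_label_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(15, 2))
        labels = rng.integers(0, 3, size=15)
        labels[:3] = [0, 1, 2]
        s1, m1 = silhouette_values(pts, labels)
        s2, m2 = silhouette_values(pts, (labels + 1) % 3)
        np.testing.assert_array_equal(s1, s2)
        assert m1 == m2


class TestSelectK:
    def test_degenerate_range_returns_that_k(self):
        rng = np.random.default_rng(0)
        e = as_embedded(rng.normal(size=(10, 2)))
        c = select_k(e, 2, 2, n_init=5, seed=0)
        assert c.K == 2 and c.selected
        assert set(c.msc_curve) == {2}

    def test_three_planted_blobs_select_three(self):
        centers = np.array([[0, 0], [30, 0], [0, 30]])
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = np.concatenate([c + rng.normal(0, 1.0, (8, 2)) for c in centers])
            c = select_k(as_embedded(pts), 2, 6, n_init=10, seed=seed)
            hits += c.K == 3
        assert hits >= 19

    def test_exact_tie_breaks_toward_smaller_k(self):
        # all points coincident: every K scores msc = 0 (a = b = 0 branch)
        e = as_embedded(np.zeros((8, 2)))
        c = select_k(e, 2, 5, n_init=3, seed=0)
        assert len(set(c.msc_curve.values())) == 1
        assert c.K == 2

    def test_empty_range_rejected(self):
        e = as_embedded(np.zeros((6, 2)))
        with pytest.raises(ParameterError):
            select_k(e, 4, 3, seed=0)


class TestClusterAllPeriods:
    def test_single_period_matches_select_k(self):
        rng = np.random.default_rng(1)
        e = as_embedded(rng.normal(size=(12, 2)))
        both = cluster_all_periods({1: e}, 2, 5, n_init=10, seed=7)
        assert both[1].K >= 2 and both[1].selected

    def test_merged_groups_drop_selected_k(self):
        """Three drift groups in period 1, two of them sharing a drift in
        period 2: the selected K drops by one."""
        from migpattern import embed_all
        from migpattern.lineage_division import LineageSet
        from migpattern.trajectory_distance import distance_matrices
        from migpattern.trajectory_prep import segment_periods

        rng = np.random.default_rng(5)
        n, block = 24, 12
        drift_1 = 5.0 * np.array([[1, 0], [-0.5, 0.9], [-0.5, -0.9]])
        drift_2 = 5.0 * np.array([[1, 0], [1, 0], [-0.5, -0.9]])  # groups 0,1 merge
        groups = np.arange(n) % 3
        steps = np.empty((n, 2 * block - 1, 2))
        for i, g in enumerate(groups):
            steps[i] = np.vstack(
                [np.tile(drift_1[g], (block - 1, 1)), np.tile(drift_2[g], (block, 1))]
            ) + rng.normal(0, 0.5, (2 * block - 1, 2))
        start = rng.normal(0, 20, (n, 1, 2))
        pos = np.concatenate([start, start + np.cumsum(steps, axis=1)], axis=1)
        lineage = LineageSet(n_slices=2 * block, trajectories={i: pos[i] for i in range(n)})
        mats = distance_matrices(segment_periods(lineage, block))
        emb = embed_all(mats, "umap", EmbeddingParams(n_neighbors=8), master_seed=2)
        cl = cluster_all_periods(emb, 2, 6, n_init=20, seed=2)
        assert cl[1].K == 3
        assert cl[2].K == 2
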