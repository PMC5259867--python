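import itertools

import numpy as np
import pytest

from dtiens.data import InteractionSet
from dtiens.imbalance import (ClusterAssignment, NegativePool,
                              PoolExhaustedError, cluster_positives,
                              oversample_clusters, oversample_rows)


def brute_force_best_2partition(X):
    """Exhaustive minimum within-cluster sum of squares over all 2-partitions."""
    n = len(X)
    best_cost, best_labels = np.inf, None
    for bits in itertools.product([0, 1], repeat=n - 1):
        labels = np.array([0, *bits])
        if labels.sum() in (0, n):
            continue
        cost = 0.0
        for c in (0, 1):
            members = X[labels == c]
            cost += ((members - members.mean(axis=0)) ** 2).sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


class TestClusterPositives:
    def test_two_blobs_match_bruteforce_partition(self):
        """On <= 8 well-separated points, K-means++ finds the optimal
        2-partition found by exhaustive enumeration."""
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0.0, 0.05, size=(5, 2)),
                       rng.normal(5.0, 0.05, size=(3, 2))])
        oracle = brute_force_best_2partition(X)
        result = cluster_positives(X, K=2, seed=1)
        same = (result.labels == oracle).all() or \
               (result.labels == 1 - oracle).all()
        assert same

    def test_k1_single_cluster(self):
        X = np.random.default_rng(1).uniform(size=(7, 3))
        a = cluster_positives(X, K=1)
        assert a.n_clusters == 1
        assert (a.labels == 0).all()

    def test_k_equals_n_each_point_own_cluster(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        a = cluster_positives(X, K=5, seed=2)
        assert a.n_clusters == 5
        assert sorted(a.labels.tolist()) == [0, 1, 2, 3, 4]

    def test_k_above_n_clamps(self):
        X = np.arange(6, dtype=float).reshape(3, 2)
        a = cluster_positives(X, K=10, seed=0)
        assert a.n_clusters <= 3
        assert len(a.labels) == 3

    def test_duplicate_points_give_k_prime_below_k(self):
        X = np.zeros((6, 2))
        X[3:] = 1.0
        a = cluster_positives(X, K=4, seed=0)
        assert a.n_clusters <= 4
        assert np.array_equal(np.unique(a.labels),
                              np.arange(a.n_clusters))

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            cluster_positives(np.zeros((3, 2)), K=0)

    def test_deterministic_for_fixed_seed(self):
        X = np.random.default_rng(4).uniform(size=(40, 5))
        a = cluster_positives(X, K=6, seed=9)
        b = cluster_positives(X, K=6, seed=9)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestOversample:
    def _assignment(self, sizes):
        labels = np.concatenate([np.full(s, c) for c, s in enumerate(sizes)])
        centroids = np.zeros((len(sizes), 1))
        return ClusterAssignment(labels, centroids)

    def test_sizes_4_2_1_grow_to_4_each(self):
        a = self._assignment([4, 2, 1])
        rows = oversample_rows(a, np.random.default_rng(0))
        assert len(rows) == 12
        grown = np.bincount(a.labels[rows])
        np.testing.assert_array_equal(grown, [4, 4, 4])

    def test_equal_sizes_identity(self):
        a = self._assignment([3, 3])
        rows = oversample_rows(a, np.random.default_rng(0))
        np.testing.assert_array_equal(np.sort(rows), np.arange(6))

    def test_singleton_cluster_duplicates_its_member(self):
        a = self._assignment([3, 1])
        rows = oversample_rows(a, np.random.default_rng(0))
        # the singleton (row 3) appears 1 original + 2 resampled times
        assert (rows == 3).sum() == 3

    def test_originals_always_retained(self):
        a = self._assignment([5, 2, 3])
        rows = oversample_rows(a, np.random.default_rng(1))
        assert set(range(10)) <= set(rows.tolist())

    def test_no_cross_cluster_contamination(self):
        """Distinct instances per output cluster equal original membership."""
        rng = np.random.default_rng(2)
        X = rng.uniform(size=(30, 4))
        a = cluster_positives(X, K=4, seed=3)
        _, rows = oversample_clusters(X, a, rng)
        out_labels = a.labels[rows]
        for c in range(a.n_clusters):
            original = set(np.where(a.labels == c)[0].tolist())
            produced = set(rows[out_labels == c].tolist())
            assert produced == original

    def test_output_matrix_matches_rows(self):
        X = np.arange(8, dtype=float).reshape(4, 2)
        a = self._assignment([3, 1])
        out, rows = oversample_clusters(X, a, np.random.default_rng(5))
        np.testing.assert_array_equal(out, X[rows])

    def test_fixed_seed_byte_identical(self):
        a = self._assignment([6, 2, 1])
        r1 = oversample_rows(a, np.random.default_rng(42))
        r2 = oversample_rows(a, np.random.default_rng(42))
        assert r1.tobytes() == r2.tobytes()


def make_pool(n_drugs, n_targets, pairs, **kw):
    drugs = [f"D{i}" for i in range(n_drugs)]
    targets = [f"T{i}" for i in range(n_targets)]
    inter = InteractionSet(pairs, drugs, targets)
    return NegativePool(inter, **kw)


class TestNegativePool:
    def test_disjoint_draws(self):
        # grid 4x3 = 12, |P| = 2 -> pool of 10
        pool = make_pool(4, 3, [("D0", "T0"), ("D1", "T1")])
        rng = np.random.default_rng(0)
        n1 = set(pool.sample(4, rng, label=0))
        n2 = set(pool.sample(4, rng, label=1))
        assert len(n1) == len(n2) == 4
        assert not n1 & n2
        assert pool.remaining == 2

    def test_draws_never_intersect_positives(self):
        pairs = [("D0", "T0"), ("D1", "T1"), ("D2", "T0")]
        pool = make_pool(5, 5, pairs)
        drawn = pool.sample(20, np.random.default_rng(1))
        assert not set(drawn) & set(pairs)

    def test_replenish_permits_overlap_and_logs(self):
        # grid\P = 10; consume 5, then ask for 8 -> replenish
        pool = make_pool(4, 3, [("D0", "T0"), ("D1", "T1")])
        rng = np.random.default_rng(2)
        first = set(pool.sample(5, rng, label=0))
        drawn = pool.sample(8, rng, label=1)
        assert len(drawn) == 8
        assert pool.draw_log[-1].replenished
        assert pool.replenish_count == 1
        assert set(drawn) & first  # overlap now permitted (8 of 10 left)

    def test_error_policy_raises_instead(self):
        pool = make_pool(4, 3, [("D0", "T0"), ("D1", "T1")],
                         policy="error")
        rng = np.random.default_rng(2)
        pool.sample(5, rng)
        with pytest.raises(PoolExhaustedError):
            pool.sample(8, rng)

    def test_exhausted_even_after_replenish_errors(self):
        pool = make_pool(2, 3, [("D0", "T0")])  # grid\P = 5
        with pytest.raises(PoolExhaustedError, match="after replenish"):
            pool.sample(8, np.random.default_rng(0))

    def test_with_replacement_policy_allows_overlap(self):
        pool = make_pool(3, 3, [("D0", "T0")],
                         policy="with_replacement")
        rng = np.random.default_rng(3)
        a = set(pool.sample(6, rng))
        b = set(pool.sample(6, rng))
        assert len(a) == len(b) == 6
        assert a & b  # 6+6 draws from 8 must overlap

    def test_excluded_pairs_never_drawn(self):
        extra = [("D2", "T2"), ("D3", "T1")]
        pool = make_pool(4, 4, [("D0", "T0")], excluded_pairs=extra)
        drawn = pool.sample(13, np.random.default_rng(4))  # everything left
        assert not set(drawn) & set(extra)

    def test_fixed_seed_byte_identical(self):
        pairs = [("D0", "T1")]
        a = make_pool(6, 6, pairs).sample(10, np.random.default_rng(7))
        b = make_pool(6, 6, pairs).sample(10, np.random.default_rng(7))
        assert a == b
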