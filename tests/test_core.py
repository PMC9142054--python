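import itertools

import numpy as np
import pytest

from kefrin import (
    CommunityCenters,
    KefrinConfig,
    Partition,
    assign_clusters,
    combined_distance,
    criterion_value,
    fit,
    initialize_seeds,
    pair_distance,
    update_centers,
)
from kefrin.core import combined_distance_matrix
from kefrin.preprocess import row_norm

from conftest import random_instance

METRICS = ("euclidean", "manhattan", "cosine")


class TestPairDistance:
    def test_hand_values(self):
        assert pair_distance([0, 0], [1, 1], "euclidean") == pytest.approx(2.0)
        assert pair_distance([0, 0], [1, 1], "manhattan") == pytest.approx(2.0)
        assert pair_distance([1, 0], [0, 1], "cosine") == pytest.approx(1.0)
        assert pair_distance([2, 3], [2, 3], "cosine") == pytest.approx(0.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            pair_distance([1, 2], [1, 2, 3], "euclidean")

    def test_unit_vectors_euclidean_is_twice_cosine(self, rng):
        for _ in range(20):
            f = row_norm(rng.normal(size=(1, 6)))[0]
            g = row_norm(rng.normal(size=(1, 6)))[0]
            de = pair_distance(f, g, "euclidean")
            dc = pair_distance(f, g, "cosine")
            assert de == pytest.approx(2 * dc, abs=1e-10)

    def test_zero_vector_cosine_distance_is_one(self):
        assert pair_distance([0, 0], [1, 2], "cosine") == pytest.approx(1.0)


class TestAssignment:
    def test_nodes_on_centers_claim_their_own(self, rng):
        Y, P = random_instance(rng, n=12, k=3)
        idx = [0, 5, 9]
        centers = CommunityCenters(Y[idx], P[idx])
        config = KefrinConfig(k=3)
        part = assign_clusters(Y, P, centers, config)
        for pos, node in enumerate(idx):
            assert part.labels[node] == pos

    def test_tie_breaks_to_smallest_index(self):
        # both centers exactly one unit away from both nodes in each space
        part = assign_clusters(
            np.zeros((2, 1)), np.zeros((2, 2)),
            CommunityCenters(np.array([[1.0], [-1.0]]), np.zeros((2, 2))),
            KefrinConfig(k=2),
        )
        assert list(part.labels) == [0, 0]

    @pytest.mark.parametrize("metric", METRICS)
    def test_matches_exhaustive_argmin_oracle(self, metric, rng):
        for n, k in [(10, 2), (30, 4)]:
            Y, P = random_instance(rng, n=n, k=k)
            centers = CommunityCenters(rng.normal(size=(k, Y.shape[1])),
                                       rng.normal(size=(k, n)))
            config = KefrinConfig(k=k, metric=metric, rho=0.7, xi=1.3)
            part = assign_clusters(Y, P, centers, config)
            for i in range(n):
                dists = [combined_distance(i, kk, Y, P, centers, config)
                         for kk in range(k)]
                assert part.labels[i] == int(np.argmin(dists))

    def test_weight_degeneracy(self, rng):
        # xi=0 ignores the network entirely; rho=0 ignores the features
        Y, P = random_instance(rng, n=15, k=2)
        centers = CommunityCenters(rng.normal(size=(2, 4)), rng.normal(size=(2, 15)))
        feat_only = assign_clusters(Y, P, centers, KefrinConfig(k=2, xi=0.0))
        feat_scrambled_net = assign_clusters(
            Y, rng.normal(size=P.shape), centers, KefrinConfig(k=2, xi=0.0)
        )
        np.testing.assert_array_equal(feat_only.labels, feat_scrambled_net.labels)
        net_only = assign_clusters(Y, P, centers, KefrinConfig(k=2, rho=0.0))
        net_scrambled_feat = assign_clusters(
            rng.normal(size=Y.shape), P, centers, KefrinConfig(k=2, rho=0.0)
        )
        np.testing.assert_array_equal(net_only.labels, net_scrambled_feat.labels)

    def test_combined_distance_additivity(self, rng):
        Y, P = random_instance(rng, n=8, k=2)
        centers = CommunityCenters(rng.normal(size=(2, 4)), rng.normal(size=(2, 8)))
        config = KefrinConfig(k=2, rho=1.0, xi=1.0)
        d = combined_distance(3, 1, Y, P, centers, config)
        dy = pair_distance(Y[3], centers.C[1], "euclidean")
        dp = pair_distance(P[3], centers.Lam[1], "euclidean")
        assert d == pytest.approx(dy + dp)


class TestCenterUpdate:
    def test_singleton_cluster_copies_node(self, rng):
        Y, P = random_instance(rng, n=5, k=2)
        part = Partition(np.array([0, 1, 1, 1, 1]), k=2)
        centers = update_centers(Y, P, part, KefrinConfig(k=2))
        np.testing.assert_allclose(centers.C[0], Y[0])
        np.testing.assert_allclose(centers.Lam[0], P[0])

    def test_pair_mean(self):
        Y = np.array([[0.0, 0.0], [2.0, 4.0]])
        P = np.zeros((2, 2))
        part = Partition(np.array([0, 0]), k=1)
        centers = update_centers(Y, P, part, KefrinConfig(k=1))
        np.testing.assert_allclose(centers.C[0], [1.0, 2.0])

    def test_cosine_centers_renormed(self):
        Y = np.array([[0.6, 0.8], [0.6, 0.8], [0.0, 1.0]])
        P = row_norm(np.ones((3, 3)))
        part = Partition(np.array([0, 0, 0]), k=1)
        centers = update_centers(Y, P, part, KefrinConfig(k=1, metric="cosine"))
        assert np.linalg.norm(centers.C[0]) == pytest.approx(1.0)
        assert np.linalg.norm(centers.Lam[0]) == pytest.approx(1.0)

    def test_median_center_option(self):
        Y = np.array([[0.0], [1.0], [10.0]])
        P = np.zeros((3, 3))
        part = Partition(np.zeros(3, dtype=int), k=1)
        config = KefrinConfig(k=1, metric="manhattan", median_centers=True)
        centers = update_centers(Y, P, part, config)
        assert centers.C[0, 0] == pytest.approx(1.0)

    def test_empty_cluster_is_internal_error(self, rng):
        Y, P = random_instance(rng, n=4, k=2)
        part = Partition(np.zeros(4, dtype=int), k=2)
        with pytest.raises(RuntimeError):
            update_centers(Y, P, part, KefrinConfig(k=2))


class TestSeedInit:
    def test_farthest_point_hand_example(self):
        # 1-D features near 0 / near 10, identity network; starting from a
        # low node, the farthest-point rule must pick node 3 next:
        # f(3) = (10.1-0.1)^2 + ||e_3 - e_1||^2 = 100 + 2, the maximum.
        Y = np.array([[0.0], [0.1], [10.0], [10.1]])
        P = np.eye(4)
        rng = np.random.default_rng(1)  # first integers(4) draw is node 1
        assert int(np.random.default_rng(1).integers(4)) == 1
        centers, seeds = initialize_seeds(Y, P, KefrinConfig(k=2), rng)
        assert seeds == [1, 3]
        np.testing.assert_allclose(centers.C, Y[[1, 3]])

    def test_k_equals_one_returns_single_node(self, rng):
        Y, P = random_instance(rng, n=6, k=2)
        centers, seeds = initialize_seeds(Y, P, KefrinConfig(k=1), rng)
        assert len(seeds) == 1
        np.testing.assert_allclose(centers.C[0], Y[seeds[0]])

    def test_deterministic_given_seed(self, rng):
        Y, P = random_instance(rng, n=25, k=4)
        config = KefrinConfig(k=4)
        _, s1 = initialize_seeds(Y, P, config, np.random.default_rng(7))
        _, s2 = initialize_seeds(Y, P, config, np.random.default_rng(7))
        assert s1 == s2

    def test_seeds_are_distinct(self, rng):
        Y, P = random_instance(rng, n=10, k=3)
        _, seeds = initialize_seeds(Y, P, KefrinConfig(k=5), rng)
        assert len(set(seeds)) == 5

    def test_k_exceeding_n_rejected(self, rng):
        Y, P = random_instance(rng, n=4, k=2)
        with pytest.raises(ValueError):
            initialize_seeds(Y, P, KefrinConfig(k=5), rng)


class TestCriterion:
    def test_zero_when_nodes_sit_on_centers(self):
        Y = np.array([[0.0, 0.0], [5.0, 5.0]])
        P = np.array([[1.0, 0.0], [0.0, 1.0]])
        part = Partition(np.array([0, 1]), k=2)
        centers = CommunityCenters(Y.copy(), P.copy())
        assert criterion_value(Y, P, part, centers, KefrinConfig(k=2)) == 0.0

    def test_single_cluster_equals_total_within_variance(self, rng):
        Y, P = random_instance(rng, n=12, k=1)
        part = Partition(np.zeros(12, dtype=int), k=1)
        config = KefrinConfig(k=1, rho=0.5, xi=2.0)
        centers = update_centers(Y, P, part, config)
        expected = 0.5 * ((Y - Y.mean(axis=0)) ** 2).sum()
        expected += 2.0 * ((P - P.mean(axis=0)) ** 2).sum()
        value = criterion_value(Y, P, part, centers, config)
        assert value == pytest.approx(expected)

    def test_merging_clusters_never_decreases_euclidean_criterion(self, rng):
        Y, P = random_instance(rng, n=8, k=2, v=2)
        config2 = KefrinConfig(k=2)
        config1 = KefrinConfig(k=1)
        whole = Partition(np.zeros(8, dtype=int), k=1)
        merged = criterion_value(Y, P, whole, update_centers(Y, P, whole, config1), config1)
        for labels in itertools.product([0, 1], repeat=8):
            labels = np.array(labels)
            if labels.min() == labels.max():
                continue
            part = Partition(labels, k=2)
            split = criterion_value(Y, P, part, update_centers(Y, P, part, config2), config2)
            assert split <= merged + 1e-9

    def test_cosine_criterion_half_of_euclidean_at_unit_vectors(self, rng):
        n, k = 10, 3
        Y = row_norm(rng.normal(size=(n, 4)))
        P = row_norm(rng.normal(size=(n, n)))
        labels = rng.integers(0, k, size=n)
        labels[:k] = np.arange(k)
        part = Partition(labels, k=k)
        # unit-norm centers: sampled node rows
        centers = CommunityCenters(Y[:k].copy(), P[:k].copy())
        ce = criterion_value(Y, P, part, centers, KefrinConfig(k=k, metric="euclidean"))
        cc = criterion_value(Y, P, part, centers, KefrinConfig(k=k, metric="cosine"))
        assert ce == pytest.approx(2 * cc, rel=1e-10)


class TestFit:
    def test_recovers_well_separated_blocks(self, easy_dataset):
        from kefrin import KefrinModel, adjusted_rand_index

        model = KefrinModel(easy_dataset.features, easy_dataset.network, k=2)
        res = model.fit(n_init=5, seed=1)
        assert adjusted_rand_index(res.labels, easy_dataset.truth) == 1.0

    @pytest.mark.parametrize("metric", METRICS)
    def test_all_clusters_nonempty(self, metric, rng):
        Y, P = random_instance(rng, n=30, k=4)
        if metric == "cosine":
            Y, P = row_norm(Y), row_norm(P)
        res = fit(Y, P, KefrinConfig(k=6, metric=metric, rng_seed=0, n_init=3))
        assert (res.partition.sizes() > 0).all()

    def test_euclidean_trajectory_non_increasing(self, rng):
        for trial in range(5):
            Y, P = random_instance(rng, n=40, k=3)
            res = fit(Y, P, KefrinConfig(k=3, rng_seed=trial))
            traj = np.array(res.criterion_trajectory)
            assert (np.diff(traj) <= 1e-8).all()

    def test_k_equals_n_gives_zero_criterion(self, rng):
        Y, P = random_instance(rng, n=6, k=2)
        res = fit(Y, P, KefrinConfig(k=6, rng_seed=0))
        assert res.criterion == pytest.approx(0.0, abs=1e-12)
        assert len(set(res.partition.labels)) == 6

    def test_identical_rows_make_k_seeds_impossible(self):
        Y = np.tile([[1.0, 2.0]], (5, 1))
        P = np.ones((5, 5))
        with pytest.raises(ValueError, match="distinct"):
            fit(Y, P, KefrinConfig(k=3, rng_seed=0))

    def test_deterministic_given_seed(self, rng):
        Y, P = random_instance(rng, n=30, k=3)
        r1 = fit(Y, P, KefrinConfig(k=3, rng_seed=11, n_init=4))
        r2 = fit(Y, P, KefrinConfig(k=3, rng_seed=11, n_init=4))
        np.testing.assert_array_equal(r1.partition.labels, r2.partition.labels)
        assert r1.criterion == r2.criterion

    def test_n_init_never_worse(self, rng):
        Y, P = random_instance(rng, n=40, k=4)
        single = fit(Y, P, KefrinConfig(k=4, rng_seed=5, n_init=1))
        multi = fit(Y, P, KefrinConfig(k=4, rng_seed=5, n_init=8))
        assert multi.criterion <= single.criterion + 1e-9

    def test_node_permutation_permutes_labels(self, rng):
        # on clearly separated data every restart reaches the same optimum,
        # so reordering the nodes must reorder the labels identically
        from kefrin import adjusted_rand_index

        n, k = 24, 3
        truth = np.repeat(np.arange(k), n // k)
        Y = truth[:, None] * 10.0 + rng.normal(scale=0.1, size=(n, 2))
        P = (truth[:, None] == truth[None, :]).astype(float)
        config = KefrinConfig(k=k, rng_seed=2, n_init=5)
        res = fit(Y, P, config)
        perm = rng.permutation(n)
        res_p = fit(Y[perm], P[perm][:, perm], config)
        assert adjusted_rand_index(res.partition.labels, truth) == 1.0
        assert adjusted_rand_index(res_p.partition.labels, truth[perm]) == 1.0

    def test_max_iter_respected(self, rng):
        Y, P = random_instance(rng, n=30, k=3)
        res = fit(Y, P, KefrinConfig(k=3, rng_seed=1, max_iter=2))
        assert res.n_iter <= 2
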