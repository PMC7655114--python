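"""Weighted stochastic block model: likelihood, inference, and partition tools."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.estimator_checks import check_estimator  # noqa: F401  (API import guard)

from netcontrol import (
    WeightedSBM,
    central_partition,
    select_k,
    variation_of_information,
    wsbm_fit,
    wsbm_log_likelihood,
)
from tests.conftest import planted_two_block, random_symmetric


def brute_log_likelihood(a, labels, p, mu, var, alpha):
    """Pair-by-pair evaluation of the mixed edge-existence/weight likelihood."""
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            r, s = labels[i] - 1, labels[j] - 1
            if a[i, j] > 0:
                total += alpha * np.log(p[r, s])
                total += (1 - alpha) * (
                    -0.5 * np.log(2 * np.pi * var[r, s])
                    - (a[i, j] - mu[r, s]) ** 2 / (2 * var[r, s])
                )
            else:
                total += alpha * np.log(1 - p[r, s])
    return total


class TestLogLikelihood:
    def test_matches_brute_force(self, rng):
        a = random_symmetric(6, rng)
        labels = np.array([1, 1, 2, 2, 1, 2])
        p = np.array([[0.6, 0.2], [0.2, 0.7]])
        mu = np.array([[1.0, 0.3], [0.3, 0.8]])
        var = np.array([[0.5, 0.2], [0.2, 0.4]])
        got = wsbm_log_likelihood(a, labels, p, mu, var, alpha=0.4)
        assert abs(got - brute_log_likelihood(a, labels, p, mu, var, 0.4)) < 1e-10

    def test_k1_alpha0_is_iid_normal(self, rng):
        a = random_symmetric(8, rng)
        w = a[np.triu_indices(8, 1)]
        w = w[w > 0]
        mu, var = 0.4, 0.09
        got = wsbm_log_likelihood(
            a, np.ones(8, dtype=int), np.array([[0.5]]),
            np.array([[mu]]), np.array([[var]]), alpha=0.0,
        )
        expect = np.sum(-0.5 * np.log(2 * np.pi * var) - (w - mu) ** 2 / (2 * var))
        assert abs(got - expect) < 1e-10

    def test_k1_alpha1_is_binomial(self, rng):
        a = random_symmetric(8, rng)
        n_pairs = 8 * 7 // 2
        n_edges = int((a[np.triu_indices(8, 1)] > 0).sum())
        p = 0.37
        got = wsbm_log_likelihood(
            a, np.ones(8, dtype=int), np.array([[p]]),
            np.array([[0.0]]), np.array([[1.0]]), alpha=1.0,
        )
        expect = n_edges * np.log(p) + (n_pairs - n_edges) * np.log(1 - p)
        assert abs(got - expect) < 1e-10

    def test_label_permutation_invariance(self, rng):
        a = random_symmetric(7, rng)
        labels = np.array([1, 2, 1, 2, 2, 1, 1])
        p = np.array([[0.6, 0.2], [0.2, 0.7]])
        mu = np.array([[1.0, 0.3], [0.3, 0.8]])
        var = np.array([[0.5, 0.2], [0.2, 0.4]])
        swapped = 3 - labels  # 1 <-> 2
        perm = {"p": p[::-1, ::-1], "mu": mu[::-1, ::-1], "var": var[::-1, ::-1]}
        a1 = wsbm_log_likelihood(a, labels, p, mu, var)
        a2 = wsbm_log_likelihood(a, swapped, perm["p"], perm["mu"], perm["var"])
        assert abs(a1 - a2) < 1e-10


class TestFit:
    def test_planted_two_block_recovery(self):
        a, labels = planted_two_block(80, seed=0)
        est = WeightedSBM(n_communities=2, n_restarts=4, random_state=0).fit(a)
        assert adjusted_rand_score(labels, est.labels_) == 1.0

    def test_elbo_monotone_within_trajectory(self):
        for seed in range(4):
            a, _ = planted_two_block(40, seed=seed)
            est = WeightedSBM(n_communities=3, n_restarts=2, random_state=seed).fit(a)
            assert np.all(np.diff(est.elbo_trajectory_) >= -1e-7)

    def test_k1_recovers_sample_moments(self, rng):
        a = random_symmetric(20, rng)
        w = a[np.triu_indices(20, 1)]
        w = w[w > 0]
        est = WeightedSBM(n_communities=1, n_restarts=1, random_state=0).fit(a)
        assert est.responsibilities_.shape == (20, 1)
        assert np.allclose(est.responsibilities_, 1.0)
        # posterior mean shrinks toward the prior (itself the sample mean)
        assert abs(est.weight_mean_[0, 0] - w.mean()) < 0.05
        assert abs(est.weight_var_[0, 0] - w.var()) < 0.5 * w.var()

    def test_same_seed_same_fit(self):
        a, _ = planted_two_block(40, seed=3)
        f1 = WeightedSBM(n_communities=2, n_restarts=3, random_state=5).fit(a)
        f2 = WeightedSBM(n_communities=2, n_restarts=3, random_state=5).fit(a)
        assert np.array_equal(f1.labels_, f2.labels_)
        assert np.allclose(f1.responsibilities_, f2.responsibilities_)
        assert f1.log_evidence_ == f2.log_evidence_

    def test_responsibility_rows_sum_to_one(self):
        a, _ = planted_two_block(40, seed=9)
        est = WeightedSBM(n_communities=4, n_restarts=2, random_state=1).fit(a)
        assert np.allclose(est.responsibilities_.sum(axis=1), 1.0)
        assert np.all(est.weight_var_ > 0)
        assert np.all((est.edge_probability_ >= 0) & (est.edge_probability_ <= 1))

    def test_k_exceeding_n_rejected(self):
        a, _ = planted_two_block(10, seed=0)
        with pytest.raises(ValueError):
            WeightedSBM(n_communities=11).fit(a)

    def test_lognormal_family_on_fat_tailed_weights(self):
        rng = np.random.default_rng(2)
        a, labels = planted_two_block(
            80, seed=2, mean_in=0.0, mean_out=0.0, sd=1e-9
        )
        # replace weights by block-dependent lognormals
        mask_in = (labels[:, None] == labels[None, :]) & (a > 0)
        mask_out = (labels[:, None] != labels[None, :]) & (a > 0)
        w = np.zeros_like(a)
        w[mask_in] = rng.lognormal(2.0, 0.3, mask_in.sum())
        w[mask_out] = rng.lognormal(-1.0, 0.3, mask_out.sum())
        w = np.triu(w, 1)
        w = w + w.T
        est = WeightedSBM(
            n_communities=2, weight_family="lognormal", n_restarts=4, random_state=0
        ).fit(w)
        assert adjusted_rand_score(labels, est.labels_) == 1.0

    def test_sklearn_param_interface(self):
        est = WeightedSBM(n_communities=3, alpha=0.7)
        params = est.get_params()
        assert params["n_communities"] == 3
        clone = WeightedSBM(**params)
        assert clone.alpha == 0.7
        a, _ = planted_two_block(30, seed=1)
        labels = est.set_params(n_restarts=2, random_state=0).fit_predict(a)
        assert labels.shape == (30,)


class TestSelectK:
    def test_recovers_planted_k3(self):
        rng = np.random.default_rng(7)
        n = 90
        labels = np.repeat([1, 2, 3], n // 3)
        iu, ju = np.triu_indices(n, 1)
        same = labels[iu] == labels[ju]
        edge = np.where(same, rng.random(len(iu)) < 0.35, rng.random(len(iu)) < 0.05)
        wts = np.abs(
            np.where(same, rng.normal(2, 0.1, len(iu)), rng.normal(0.5, 0.1, len(iu)))
        )
        a = np.zeros((n, n))
        a[iu, ju] = edge * wts
        a = a + a.T
        best_k, fits = select_k(a, range(1, 7), seed=0, n_restarts=3)
        assert best_k == 3
        assert fits[3].log_evidence_ > fits[1].log_evidence_

    def test_singleton_grid(self):
        a, _ = planted_two_block(30, seed=4)
        best_k, fits = select_k(a, [2], seed=0, n_restarts=2)
        assert best_k == 2 and set(fits) == {2}

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            select_k(np.zeros((4, 4)), [])


class TestPartitionDistance:
    def test_identical_and_relabeled_partitions(self):
        p = np.array([1, 1, 2, 2, 3])
        assert variation_of_information(p, p) < 1e-12
        assert variation_of_information(p, np.array([5, 5, 9, 9, 1])) < 1e-12

    def test_independent_random_bipartitions(self):
        rng = np.random.default_rng(0)
        p1 = rng.integers(1, 3, 1000)
        p2 = rng.integers(1, 3, 1000)
        vi = variation_of_information(p1, p2)
        assert abs(vi - 2 * np.log(2)) < 0.1  # MI ~ 0, entropies ~ ln 2

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            variation_of_information([1, 2], [1, 2, 3])

    def test_central_partition_majority(self):
        p = np.array([1, 1, 2, 2])
        q = np.array([1, 2, 1, 2])
        assert np.array_equal(central_partition([p, p, q]), p)
        assert np.array_equal(central_partition([q, p, p]), p)

    def test_central_partition_matches_brute_force(self, rng):
        parts = [rng.integers(1, 4, 30) for _ in range(7)]
        dist = np.zeros((7, 7))
        for i in range(7):
            for j in range(7):
                dist[i, j] = variation_of_information(parts[i], parts[j])
        expect = parts[int(np.argmin(dist.sum(axis=1)))]
        assert np.array_equal(central_partition(parts), expect)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            central_partition([])


def test_wsbm_fit_wrapper():
    a, labels = planted_two_block(50, seed=6)
    est = wsbm_fit(a, 2, seed=0, n_restarts=3)
    assert adjusted_rand_score(labels, est.labels_) == 1.0
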