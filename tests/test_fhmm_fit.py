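"""Baum-Welch EM, functional k-means, the subsampling consensus
initialisation, centroid grouping, and state relabelling."""

import itertools

import numpy as np
import pytest

import statefda as sf
from statefda.core import Curve
from statefda.fhmm import (
    CentroidPool,
    baum_welch,
    functional_kmeans,
    group_centroids,
    l2_distance,
    make_initial_model,
    relabel_states,
    subsample_initialise,
    viterbi,
)
from scipy.optimize import linear_sum_assignment


def match_centroids(true_model, fitted):
    """Hungarian matching of fitted to true centroids; returns matched
    distances and the permutation."""
    D = np.array(
        [[l2_distance(a, b) for b in fitted.centroids] for a in true_model.centroids]
    )
    rows, cols = linear_sum_assignment(D)
    return D[rows, cols], cols


class TestBaumWelch:
    def test_fixed_point_at_truth_on_noiseless_data(self, grid):
        # deterministic cyclic chain: the only possible path is the true
        # one, so one EM pass must reproduce the model exactly
        centroids = sf.make_psd_centroids(grid, 4)
        A = np.roll(np.eye(4), 1, axis=1)  # 1->2->3->4->1
        truth = sf.FHMMModel(4, [1, 0, 0, 0], A, centroids)
        data, _ = sf.simulate_fhmm_dataset(truth, 5, 12, noise_sd=0.0, seed=0)
        fitted, _ = baum_welch(data, truth, max_iter=1)
        assert np.abs(fitted.initial_distribution - truth.initial_distribution).max() < 1e-8
        assert np.abs(fitted.transition_matrix - truth.transition_matrix).max() < 1e-8
        assert np.abs(fitted.centroid_matrix() - truth.centroid_matrix()).max() < 1e-8

    def test_objective_history_nondecreasing(self, simulated, four_state_truth):
        data, _ = simulated
        init = make_initial_model(
            functional_kmeans([c for s in data for c in s.curves], 4, seed=0)
        )
        _, history = baum_welch(data, init)
        diffs = np.diff(history.objective)
        assert np.all(diffs >= -1e-9)

    def test_distributions_remain_valid_after_every_m_step(self, simulated):
        data, _ = simulated
        init = make_initial_model(
            functional_kmeans([c for s in data for c in s.curves], 4, seed=1)
        )
        model, _ = baum_welch(data, init, max_iter=7)
        assert model.initial_distribution.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(model.transition_matrix.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(model.initial_distribution >= 0)
        assert np.all(model.transition_matrix >= 0)

    def test_three_well_separated_states_recovered(self, grid):
        spec = [[(4.0, 1.0, 1.0)], [(14.0, 1.0, 1.2)], [(25.0, 1.0, 1.5)]]
        centroids = sf.make_psd_centroids(grid, 3, spec=spec)
        dmin = min(
            l2_distance(a, b) for a, b in itertools.combinations(centroids, 2)
        )
        A = np.full((3, 3), 0.05)
        np.fill_diagonal(A, 0.9)
        truth = sf.FHMMModel(3, np.full(3, 1 / 3), A, centroids)
        data, _ = sf.simulate_fhmm_dataset(truth, 50, 100, noise_sd=0.1, seed=21)
        init = make_initial_model(
            functional_kmeans([c for s in data for c in s.curves], 3, seed=21)
        )
        fitted, _ = baum_welch(data, init)
        dists, perm = match_centroids(truth, fitted)
        assert np.all(dists < 0.1 * dmin)
        assert np.abs(
            fitted.transition_matrix[np.ix_(perm, perm)] - A
        ).max() < 0.05

    def test_label_permutation_equivariance(self, simulated):
        data, truth = simulated
        model = truth.model
        init = make_initial_model([c.copy() for c in model.centroids])
        fit_a, hist_a = baum_welch(data, init, max_iter=5)
        perm = [2, 0, 3, 1]
        init_p = sf.FHMMModel(
            4,
            init.initial_distribution[perm],
            init.transition_matrix[np.ix_(perm, perm)],
            [init.centroids[i].copy() for i in perm],
        )
        fit_b, hist_b = baum_welch(data, init_p, max_iter=5)
        assert hist_a.objective[-1] == pytest.approx(hist_b.objective[-1], abs=1e-6)
        assert np.allclose(
            fit_a.centroid_matrix()[perm], fit_b.centroid_matrix(), atol=1e-8
        )
        assert np.allclose(
            fit_a.transition_matrix[np.ix_(perm, perm)],
            fit_b.transition_matrix,
            atol=1e-8,
        )


class TestFunctionalKmeans:
    def test_k_one_returns_pointwise_mean(self, grid):
        rng = np.random.default_rng(0)
        curves = [Curve(grid, rng.normal(size=len(grid))) for _ in range(20)]
        (c,) = functional_kmeans(curves, 1, seed=0)
        mean = np.mean([x.values for x in curves], axis=0)
        assert np.abs(c.values - mean).max() < 1e-10

    def test_two_tight_bundles_recovered(self, grid):
        rng = np.random.default_rng(1)
        base = sf.make_psd_centroids(grid, 2, spec=[[(5, 1, 1)], [(25, 1, 1)]])
        curves = [
            Curve(grid, base[i % 2].values + 0.01 * rng.normal(size=len(grid)))
            for i in range(40)
        ]
        cents = functional_kmeans(curves, 2, seed=1)
        dists, _ = match_centroids(
            sf.FHMMModel(2, [0.5, 0.5], np.eye(2), base),
            sf.FHMMModel(2, [0.5, 0.5], np.eye(2), cents),
        )
        assert np.all(dists < 0.05)

    def test_identical_curves_collapse_to_that_curve(self, grid):
        c = Curve(grid, np.sin(grid.points))
        with pytest.warns(Warning):
            cents = functional_kmeans([c.copy() for _ in range(10)], 3, seed=2)
        for cent in cents:
            assert np.abs(cent.values - c.values).max() < 1e-10

    def test_k_larger_than_curve_count_rejected(self, grid):
        c = Curve(grid, np.zeros(len(grid)))
        with pytest.raises(ValueError):
            functional_kmeans([c, c.copy()], 3, seed=0)


class TestSubsampleInitialise:
    def test_pool_size_and_subsample_arithmetic(self, four_state_truth):
        data, _ = sf.simulate_fhmm_dataset(four_state_truth, 10, 30, noise_sd=0.1, seed=2)
        pool = subsample_initialise(
            data, n_models=3, states_per_model=5, seed=2,
            baum_welch_kwargs={"max_iter": 3},
        )
        assert len(pool) == 15
        assert pool.provenance[0] == (1, 1)
        assert {m for m, _ in pool.provenance} == {1, 2, 3}
        # floor(0.8 * 10) = 8 individuals per subsample is a precondition
        # of the draw itself; check the fraction bound errors instead
        with pytest.raises(ValueError):
            subsample_initialise(data, subsample_fraction=1.0)

    def test_pool_contains_neighbour_of_every_true_centroid(
        self, four_state_truth, min_centroid_distance
    ):
        data, _ = sf.simulate_fhmm_dataset(
            four_state_truth, 15, 60, noise_sd=0.1, seed=3
        )
        pool = subsample_initialise(
            data, n_models=4, states_per_model=6, seed=3
        )
        for mu in four_state_truth.centroids:
            best = min(l2_distance(mu, c) for c in pool.centroids)
            assert best < 0.1 * min_centroid_distance


class TestGroupCentroids:
    def test_identical_pool_collapses_to_one_group(self, grid):
        c = Curve(grid, np.sin(grid.points))
        pool = CentroidPool([c.copy() for _ in range(6)], [(1, i) for i in range(6)])
        res = group_centroids(pool, distance_threshold=0.5)
        assert len(res.groups) == 1
        assert np.abs(res.initial_centroids[0].values - c.values).max() < 1e-12

    def test_two_separated_clusters_found(self, grid):
        rng = np.random.default_rng(4)
        a, b = sf.make_psd_centroids(grid, 2, spec=[[(5, 1, 1)], [(25, 1, 1)]])
        pool_curves = [
            Curve(grid, (a if i < 5 else b).values + 0.01 * rng.normal(size=len(grid)))
            for i in range(10)
        ]
        pool = CentroidPool(pool_curves, [(1, i) for i in range(10)])
        res = group_centroids(pool, n_groups=2)
        groups = [set(v) for v in res.groups.values()]
        assert {frozenset(range(5)), frozenset(range(5, 10))} == {
            frozenset(g) for g in groups
        }

    def test_manual_labels_applied_verbatim_and_must_cover(self, grid):
        c = Curve(grid, np.zeros(len(grid)))
        pool = CentroidPool([c.copy() for _ in range(4)], [(1, i) for i in range(4)])
        res = group_centroids(pool, method="manual",
                              manual_labels={0: 7, 1: 7, 2: 9, 3: 9})
        assert len(res.groups) == 2
        with pytest.raises(ValueError, match="cover"):
            group_centroids(pool, method="manual", manual_labels={0: 1})

    def test_exactly_one_selector_required(self, grid):
        c = Curve(grid, np.zeros(len(grid)))
        pool = CentroidPool([c.copy()], [(1, 1)])
        with pytest.raises(ValueError, match="exactly one"):
            group_centroids(pool)
        with pytest.raises(ValueError, match="exactly one"):
            group_centroids(pool, n_groups=1, distance_threshold=0.1)


class TestRelabelStates:
    def test_states_reordered_by_allocation(self, simulated, four_state_truth):
        data, _ = simulated
        paths = [viterbi(s, four_state_truth) for s in data]
        model, new_paths = relabel_states(four_state_truth, paths)
        counts = np.zeros(4, int)
        for p in new_paths:
            counts += np.bincount(p.states - 1, minlength=4)
        assert np.all(np.diff(counts) <= 0)

    def test_already_ordered_is_identity(self, grid):
        centroids = sf.make_psd_centroids(grid, 2, spec=[[(5, 1, 1)], [(25, 1, 1)]])
        model = sf.FHMMModel(2, [0.6, 0.4], [[0.9, 0.1], [0.1, 0.9]], centroids)
        paths = [sf.ViterbiPath("a", np.array([1, 1, 1, 2]), 0.0)]
        new_model, new_paths = relabel_states(model, paths)
        assert np.array_equal(new_paths[0].states, paths[0].states)
        assert np.array_equal(new_model.centroid_matrix(), model.centroid_matrix())

    def test_invariants_preserved_under_relabelling(self, simulated, four_state_truth):
        from statefda.fhmm import forward_backward

        data, _ = simulated
        paths = [viterbi(s, four_state_truth) for s in data]
        before = sum(
            forward_backward(s, four_state_truth).log_pseudo_likelihood for s in data
        )
        model, new_paths = relabel_states(four_state_truth, paths)
        after = sum(forward_backward(s, model).log_pseudo_likelihood for s in data)
        assert after == pytest.approx(before, abs=1e-8)
        counts_before = sorted(
            np.concatenate([p.states for p in paths]).tolist().count(i) for i in range(1, 5)
        )
        counts_after = sorted(
            np.concatenate([p.states for p in new_paths]).tolist().count(i)
            for i in range(1, 5)
        )
        assert counts_before == counts_after
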