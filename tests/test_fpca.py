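"""Within-state FPCA: eigen-structure, scores, retention, aggregation."""

import numpy as np
import pytest

from statefda.core import Curve, FrequencyGrid, FunctionalSeries
from statefda.fhmm import ViterbiPath, viterbi
from statefda.fpca import (
    choose_n_components,
    fit_fpca,
    fpca_weights,
    individual_mean_scores,
    project_scores,
    subset_by_state,
)
from statefda.smooth import BasisSystem


@pytest.fixture(scope="module")
def unit_grid():
    return FrequencyGrid(np.linspace(0.0, 1.0, 41))


def orthonormal_pair(grid):
    """Two L2-orthonormal functions on the grid (sin/cos harmonics)."""
    t = grid.points
    phi1 = np.sqrt(2.0) * np.sin(2 * np.pi * t)
    phi2 = np.sqrt(2.0) * np.cos(2 * np.pi * t)
    return phi1, phi2


class TestSubsetByState:
    def test_constant_paths_select_everything_or_nothing(self, simulated):
        data, _ = simulated
        paths = [
            ViterbiPath(s.individual_id, np.ones(len(s), int), 0.0) for s in data
        ]
        all_curves = subset_by_state(data, paths, 1)
        assert len(all_curves) == sum(len(s) for s in data)
        assert subset_by_state(data, paths, 2) == []

    def test_selects_by_time_position(self, grid):
        curves = [Curve(grid, np.zeros(len(grid)), time_index=k) for k in range(3)]
        series = FunctionalSeries("a", curves)
        paths = [ViterbiPath("a", np.array([1, 2, 1]), 0.0)]
        sel = subset_by_state([series], paths, 1)
        assert [c.time_index for c in sel] == [0, 2]

    def test_state_subsets_partition_dataset(self, simulated, four_state_truth):
        data, _ = simulated
        paths = [viterbi(s, four_state_truth) for s in data]
        total = sum(len(subset_by_state(data, paths, s)) for s in range(1, 5))
        assert total == sum(len(s) for s in data)

    def test_misaligned_paths_rejected(self, simulated):
        data, _ = simulated
        paths = [ViterbiPath(s.individual_id, np.ones(len(s) - 1, int), 0.0)
                 for s in data]
        with pytest.raises(ValueError, match="length"):
            subset_by_state(data, paths, 1)


class TestFitFpca:
    def test_identical_curves_are_pure_mean(self, unit_grid):
        c = Curve(unit_grid, np.sin(unit_grid.points * 3))
        saturated = BasisSystem.for_grid(unit_grid, n_basis=len(unit_grid))
        model = fit_fpca([c.copy() for _ in range(5)], basis=saturated, penalty=0.0)
        assert np.abs(model.mean_function.values - c.values).max() < 1e-8
        assert np.all(model.eigenvalues < 1e-16)
        assert np.abs(model.scores).max() < 1e-8

    def test_mirror_pair_gives_rank_one_covariance(self, unit_grid):
        base = np.sin(unit_grid.points * 2)
        dev = np.cos(unit_grid.points * 5)
        curves = [Curve(unit_grid, base + dev), Curve(unit_grid, base - dev)]
        model = fit_fpca(curves, penalty=0.0)
        assert model.eigenvalues[0] > 1e-6
        assert np.all(model.eigenvalues[1:] < 1e-10 * model.eigenvalues[0])
        assert model.variance_fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_two_component_variance_share_recovery(self, unit_grid):
        rng = np.random.default_rng(0)
        phi1, phi2 = orthonormal_pair(unit_grid)
        mu = unit_grid.points**2
        n = 500
        a1 = rng.normal(0, 2.0, n)  # var 4
        a2 = rng.normal(0, 1.0, n)  # var 1
        curves = [Curve(unit_grid, mu + a1[i] * phi1 + a2[i] * phi2) for i in range(n)]
        model = fit_fpca(curves, penalty=0.0)
        assert model.variance_fractions[0] == pytest.approx(0.8, abs=0.03)
        assert model.variance_fractions[1] == pytest.approx(0.2, abs=0.03)
        w = fpca_weights(unit_grid)
        for truth in (phi1, phi2):
            errs = [
                min(
                    np.sqrt(np.sum(w * (f.values - truth) ** 2)),
                    np.sqrt(np.sum(w * (f.values + truth) ** 2)),
                )
                for f in model.eigenfunctions[:2]
            ]
            assert min(errs) < 0.05

    def test_eigenfunctions_orthonormal_under_quadrature(self, simulated):
        data, _ = simulated
        curves = [c for s in data[:10] for c in s.curves]
        model = fit_fpca(curves)
        w = fpca_weights(model.grid)
        F = model.eigenfunction_matrix()
        gram = (F * w) @ F.T
        assert np.abs(gram - np.eye(len(F))).max() < 1e-6

    def test_discrete_limit_matches_classical_pca(self, unit_grid):
        rng = np.random.default_rng(5)
        Y = rng.standard_normal((60, len(unit_grid)))
        curves = [Curve(unit_grid, y) for y in Y]
        saturated = BasisSystem.for_grid(unit_grid, n_basis=len(unit_grid))
        model = fit_fpca(curves, basis=saturated, penalty=0.0)
        Yc = Y - Y.mean(axis=0)
        _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
        classical = Yc @ Vt.T * np.sqrt(unit_grid.spacing)
        for c in range(5):
            err = min(
                np.abs(model.scores[:, c] - classical[:, c]).max(),
                np.abs(model.scores[:, c] + classical[:, c]).max(),
            )
            assert err < 1e-6

    def test_fewer_than_two_curves_rejected(self, unit_grid):
        with pytest.raises(ValueError):
            fit_fpca([Curve(unit_grid, np.zeros(len(unit_grid)))])

    def test_eigenvalues_nonincreasing_and_sign_convention(self, simulated):
        data, _ = simulated
        curves = [c for s in data[:8] for c in s.curves]
        model = fit_fpca(curves)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        for f in model.eigenfunctions:
            assert f.values[np.argmax(np.abs(f.values))] > 0


class TestChooseNComponents:
    def test_threshold_crossing_arithmetic(self):
        assert choose_n_components([0.4, 0.25, 0.10, 0.1, 0.15], 0.70) == 3
        assert choose_n_components([0.71, 0.29], 0.70) == 1

    def test_published_state_profile_retains_five_components(self):
        # per-component shares 22.6/17.1/13.6/11.5/7.8 percent reach a
        # 72.6% cumulative share at the fifth component
        fractions = [0.226, 0.171, 0.136, 0.115, 0.078]
        remainder = 1.0 - sum(fractions)
        fractions = fractions + [remainder]
        assert choose_n_components(fractions, 0.70) == 5
        assert sum(fractions[:5]) == pytest.approx(0.726, abs=1e-12)

    def test_never_exceeding_threshold_warns_and_keeps_all(self):
        with pytest.warns(RuntimeWarning, match="never exceeds"):
            assert choose_n_components([0.3, 0.3], 0.70) == 2


class TestProjectScores:
    def test_mean_curve_scores_zero(self, unit_grid):
        rng = np.random.default_rng(2)
        curves = [Curve(unit_grid, rng.standard_normal(len(unit_grid)))
                  for _ in range(20)]
        model = fit_fpca(curves, penalty=0.0)
        scores = project_scores(model, [model.mean_function])
        assert np.abs(scores).max() < 1e-8

    def test_mean_plus_two_phi_one(self, unit_grid):
        rng = np.random.default_rng(3)
        curves = [Curve(unit_grid, rng.standard_normal(len(unit_grid)))
                  for _ in range(20)]
        model = fit_fpca(curves, penalty=0.0)
        probe = Curve(
            unit_grid, model.mean_function.values + 2.0 * model.eigenfunctions[0].values
        )
        scores = project_scores(model, [probe])[0]
        assert scores[0] == pytest.approx(2.0, abs=1e-8)
        assert np.abs(scores[1:]).max() < 1e-8

    def test_training_scores_reproduced(self, simulated):
        data, _ = simulated
        curves = [c for s in data[:6] for c in s.curves]
        model = fit_fpca(curves)
        assert np.abs(project_scores(model, curves) - model.scores).max() < 1e-8

    def test_reconstruction_error_nonincreasing_in_components(self, unit_grid):
        rng = np.random.default_rng(4)
        curves = [Curve(unit_grid, rng.standard_normal(len(unit_grid)))
                  for _ in range(30)]
        model = fit_fpca(curves, penalty=0.0)
        w = fpca_weights(unit_grid)
        x = curves[0].values
        errs = []
        for C in range(1, 8):
            recon = model.mean_function.values + (
                model.scores[0, :C] @ model.eigenfunction_matrix()[:C]
            )
            errs.append(np.sqrt(np.sum(w * (x - recon) ** 2)))
        assert np.all(np.diff(errs) <= 1e-10)


class TestIndividualMeanScores:
    def test_single_observation_individuals_pass_through(self, unit_grid):
        rng = np.random.default_rng(6)
        curves = [
            Curve(unit_grid, rng.standard_normal(len(unit_grid)),
                  individual_id=f"p{i}", time_index=0)
            for i in range(6)
        ]
        model = fit_fpca(curves, penalty=0.0)
        table = individual_mean_scores(model, n_components=2)
        for i, (pid, _) in enumerate(model.obs_ids):
            assert table.loc[pid, "fpc_score_1"] == pytest.approx(model.scores[i, 0])

    def test_mean_of_two_observations(self, unit_grid):
        rng = np.random.default_rng(7)
        curves = [
            Curve(unit_grid, rng.standard_normal(len(unit_grid)),
                  individual_id="p1", time_index=k)
            for k in range(2)
        ] + [
            Curve(unit_grid, rng.standard_normal(len(unit_grid)),
                  individual_id="p2", time_index=k)
            for k in range(3)
        ]
        model = fit_fpca(curves, penalty=0.0)
        table = individual_mean_scores(model, n_components=1)
        assert table.loc["p1", "fpc_score_1"] == pytest.approx(
            model.scores[:2, 0].mean()
        )

    def test_invariant_to_observation_order(self, unit_grid):
        rng = np.random.default_rng(8)
        curves = [
            Curve(unit_grid, rng.standard_normal(len(unit_grid)),
                  individual_id=f"p{i % 4}", time_index=i)
            for i in range(16)
        ]
        m1 = fit_fpca(curves, penalty=0.0)
        t1 = individual_mean_scores(m1, n_components=2)
        shuffled = [curves[i] for i in rng.permutation(16)]
        m2 = fit_fpca(shuffled, penalty=0.0)
        t2 = individual_mean_scores(m2, n_components=2)
        assert np.allclose(t1.to_numpy(), t2.to_numpy(), atol=1e-10)
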