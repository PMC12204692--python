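"""Shared fixtures: grids, well-separated truth models, simulated data."""

import itertools

import numpy as np
import pytest

import statefda as sf
from statefda.fhmm import l2_distance


@pytest.fixture(scope="session")
def grid():
    return sf.default_grid()


@pytest.fixture(scope="session")
def four_state_truth(grid):
    """Sticky 4-state truth model over the default EEG-like centroids."""
    centroids = sf.make_psd_centroids(grid, 4)
    A = np.full((4, 4), 0.1 / 3)
    np.fill_diagonal(A, 0.9)
    return sf.FHMMModel(
        n_states=4,
        initial_distribution=np.full(4, 0.25),
        transition_matrix=A,
        centroids=centroids,
    )


@pytest.fixture(scope="session")
def min_centroid_distance(four_state_truth):
    return min(
        l2_distance(a, b)
        for a, b in itertools.combinations(four_state_truth.centroids, 2)
    )


@pytest.fixture(scope="session")
def simulated(four_state_truth):
    """Moderate simulated dataset: 30 individuals x 60 steps, light noise."""
    return sf.simulate_fhmm_dataset(
        four_state_truth, n_individuals=30, seq_length=60, noise_sd=0.1, seed=42
    )


def random_small_instance(rng, n_states=None, seq_len=None, n_grid=7):
    """Random tiny FHMM instance + series for brute-force comparisons."""
    N = n_states or int(rng.integers(1, 4))
    K = seq_len or int(rng.integers(1, 7))
    g = sf.FrequencyGrid(np.sort(rng.uniform(0, 1, n_grid) + np.arange(n_grid)))
    centroids = [sf.Curve(g, rng.normal(size=n_grid)) for _ in range(N)]
    nu = rng.dirichlet(np.ones(N))
    A = rng.dirichlet(np.ones(N), size=N)
    model = sf.FHMMModel(N, nu, A, centroids)
    curves = [sf.Curve(g, rng.normal(size=n_grid), time_index=k) for k in range(K)]
    series = sf.FunctionalSeries("x", curves)
    return model, series
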