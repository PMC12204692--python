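"""Synthetic data generation for the full pipeline.

Two generators are provided:

* :func:`simulate_fhmm_dataset` draws multi-individual sequences of
  curves from a known functional hidden Markov model — a Markov chain
  over a small set of latent states, each emitting its centroid curve
  plus smooth functional noise — so that every downstream stage
  (initialisation, EM, decoding, occupancy, FPCA) can be tested against
  ground truth.
* :func:`simulate_raw_psd` builds raw log10-power spectra as an
  aperiodic 1/f component plus Gaussian oscillatory peaks plus noise,
  the input the spectral parameteriser expects.

Centroid presets mimic the qualitative state profiles seen in
resting-state EEG: a delta-dominant state with elevated high-beta, a
theta state with a low (9 Hz) alpha peak, a high-alpha (11 Hz) state
with elevated beta-1, and a strong 10 Hz alpha state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable, Sequence

import numpy as np
from scipy.interpolate import BSpline

from .core import Curve, FrequencyGrid, FunctionalSeries, default_grid

__all__ = [
    "SimulationTruth",
    "make_psd_centroids",
    "default_state_peaks",
    "simulate_fhmm_dataset",
    "simulate_raw_psd",
]

#: Per-state Gaussian peak sets (center Hz, amplitude, sd Hz) for the
#: default 4-state preset.  Ordered as: delta + beta-2; theta + 9 Hz
#: alpha; 11 Hz alpha + beta-1; strong 10 Hz alpha.
_DEFAULT_STATE_PEAKS: list[list[tuple[float, float, float]]] = [
    [(2.0, 0.9, 1.2), (26.0, 0.35, 2.5)],
    [(5.5, 0.5, 1.2), (9.0, 0.45, 1.0)],
    [(11.0, 0.45, 1.0), (18.0, 0.35, 2.0)],
    [(10.0, 1.0, 1.2)],
]


def default_state_peaks() -> list[list[tuple[float, float, float]]]:
    """Peak parameter sets of the default 4-state centroid preset."""
    return [list(p) for p in _DEFAULT_STATE_PEAKS]


@dataclass
class SimulationTruth:
    """Ground truth of a simulated dataset."""

    model: "FHMMModel"  # noqa: F821 - forward ref, resolved at runtime
    paths: dict[Hashable, np.ndarray]
    noise_sd: float
    seed: int


def _gaussian_sum(
    points: np.ndarray, peaks: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    out = np.zeros_like(points)
    for center, amp, sd in peaks:
        out += amp * np.exp(-0.5 * ((points - center) / sd) ** 2)
    return out


def make_psd_centroids(
    grid: FrequencyGrid | None = None,
    n_states: int = 4,
    spec: Sequence[Sequence[tuple[float, float, float]]] | None = None,
) -> list[Curve]:
    """Build latent-state centroid curves as sums of Gaussian peaks.

    Parameters
    ----------
    grid
        Functional domain; defaults to the 1.5--30 Hz analysis grid.
    n_states
        Number of latent states.
    spec
        One peak list per state, each peak a ``(center, amplitude, sd)``
        triple with the center inside the grid range.  A state may have
        an empty peak list (all-zero centroid).  Defaults to the
        4-state EEG-like preset when ``n_states == 4``.
    """
    grid = grid if grid is not None else default_grid()
    if n_states < 1:
        raise ValueError("n_states must be positive")
    if spec is None:
        if n_states != len(_DEFAULT_STATE_PEAKS):
            raise ValueError(
                "no default peak preset for n_states="
                f"{n_states}; pass an explicit spec"
            )
        spec = _DEFAULT_STATE_PEAKS
    if len(spec) != n_states:
        raise ValueError(f"spec lists {len(spec)} states, expected {n_states}")
    lo, hi = float(grid.points[0]), float(grid.points[-1])
    for i, peaks in enumerate(spec):
        for center, _amp, sd in peaks:
            if not (lo <= center <= hi):
                raise ValueError(
                    f"state {i + 1}: peak center {center} outside grid "
                    f"range [{lo}, {hi}]"
                )
            if sd <= 0:
                raise ValueError(f"state {i + 1}: peak sd must be positive")
    return [Curve(grid, _gaussian_sum(grid.points, peaks)) for peaks in spec]


def _smooth_noise_basis(grid: FrequencyGrid, n_basis: int = 10) -> np.ndarray:
    """(G, n_basis) cubic B-spline design matrix with unit pointwise
    marginal variance under i.i.d. standard-normal coefficients."""
    order = 4
    lo, hi = float(grid.points[0]), float(grid.points[-1])
    n_interior = n_basis - order
    if n_interior < 0:
        raise ValueError("need at least 4 basis functions for cubic noise")
    interior = np.linspace(lo, hi, n_interior + 2)[1:-1]
    knots = np.concatenate([np.repeat(lo, order), interior, np.repeat(hi, order)])
    design = BSpline.design_matrix(grid.points, knots, order - 1).toarray()
    scale = np.sqrt(np.sum(design**2, axis=1))
    return design / scale[:, None]


def simulate_fhmm_dataset(
    truth_model: "FHMMModel",  # noqa: F821
    n_individuals: int,
    seq_length: int,
    noise_sd: float = 0.05,
    noise_smoothness: float = 10.0,
    seed: int = 0,
) -> tuple[list[FunctionalSeries], SimulationTruth]:
    """Simulate multi-individual curve sequences from a known FHMM.

    For each individual a state path is drawn from the chain
    ``(nu, A)`` and each emitted curve is the current state's centroid
    plus smooth zero-mean functional noise: independent Gaussian
    coefficients on ``round(noise_smoothness)`` evenly spaced cubic
    basis functions, interpolated to the grid and rescaled so the
    pointwise marginal standard deviation equals ``noise_sd``.

    A single seed sequence is split per individual, so any individual's
    data is reproducible regardless of how many others are simulated.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be positive")
    if seq_length < 1:
        raise ValueError("seq_length must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    truth_model.validate()
    grid = truth_model.grid
    centroids = truth_model.centroid_matrix()
    n_states = truth_model.n_states
    noise_design = _smooth_noise_basis(grid, n_basis=max(4, round(noise_smoothness)))

    child_seeds = np.random.SeedSequence(seed).spawn(n_individuals)
    dataset: list[FunctionalSeries] = []
    paths: dict[Hashable, np.ndarray] = {}
    for p, child in enumerate(child_seeds, start=1):
        rng = np.random.default_rng(child)
        states = np.empty(seq_length, dtype=int)
        states[0] = rng.choice(n_states, p=truth_model.initial_distribution)
        for k in range(1, seq_length):
            states[k] = rng.choice(
                n_states, p=truth_model.transition_matrix[states[k - 1]]
            )
        coefs = rng.standard_normal((seq_length, noise_design.shape[1]))
        noise = noise_sd * coefs @ noise_design.T
        values = centroids[states] + noise
        pid = f"sim{p:04d}"
        curves = [
            Curve(grid, values[k], individual_id=pid, time_index=k + 1)
            for k in range(seq_length)
        ]
        dataset.append(FunctionalSeries(pid, curves))
        paths[pid] = states + 1  # 1-based state labels
    truth = SimulationTruth(
        model=truth_model, paths=paths, noise_sd=noise_sd, seed=seed
    )
    return dataset, truth


def simulate_raw_psd(
    grid: FrequencyGrid,
    offset: float,
    exponent: float,
    peaks: Sequence[tuple[float, float, float]] = (),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> Curve:
    """Simulate a raw log10-power spectrum.

    The curve is ``offset - exponent * log10(f)`` (the aperiodic 1/f
    background in log-log space) plus a sum of Gaussian peaks plus
    i.i.d. Gaussian noise of standard deviation ``noise_sd``.
    """
    if np.any(grid.points <= 0):
        raise ValueError("frequencies must be strictly positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    values = offset - exponent * np.log10(grid.points)
    values = values + _gaussian_sum(grid.points, peaks)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_sd * rng.standard_normal(len(grid))
    return Curve(grid, values)
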