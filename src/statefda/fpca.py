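"""Functional principal component analysis on within-state curve sets.

Curves decoded into one latent state are pooled, represented by
penalised B-spline smooths, and decomposed into a mean function plus
orthonormal eigenfunctions of the covariance operator.  Each curve
gets a score per component (its coordinate along that mode of
variation); scores are aggregated per individual for downstream
regression.

Numerics: all L2 inner products in the eigenproblem and the scores
use a fixed Riemann-sum quadrature on the observation grid (weight =
grid spacing on uniform grids, trapezoid weights otherwise).  This
makes the functional eigenproblem exactly a weighted matrix PCA: with
zero penalty and a saturated basis the scores equal classical PCA
scores of the discretised curves times the square root of the grid
spacing.  Smoothing affects the mean and covariance estimates only;
scores project the raw curves, so projecting the training set
reproduces the stored scores exactly.  Eigenfunction signs are fixed
by making each function's largest-magnitude value positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Curve, FrequencyGrid, FunctionalSeries, stack_values, trapezoid_weights
from .fhmm import ViterbiPath
from .smooth import BasisSystem, _solve_penalised

__all__ = [
    "FPCAModel",
    "subset_by_state",
    "fit_fpca",
    "choose_n_components",
    "scree_data",
    "project_scores",
    "individual_mean_scores",
]

DEFAULT_PENALTY = 1e-4
RETENTION_THRESHOLD = 0.70


def fpca_weights(grid: FrequencyGrid) -> np.ndarray:
    """Quadrature weights of the FPCA inner product."""
    if grid.is_uniform():
        return np.full(len(grid), grid.spacing)
    return trapezoid_weights(grid)


@dataclass
class FPCAModel:
    """Fitted FPCA decomposition for one curve set."""

    state_label: Hashable
    mean_function: Curve
    eigenfunctions: list[Curve]
    eigenvalues: np.ndarray
    scores: np.ndarray  # (n_obs, n_components)
    variance_fractions: np.ndarray
    n_retained: int
    basis: BasisSystem
    penalty: float
    obs_ids: list[tuple[Hashable, int | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, float)
        if np.any(ev < -1e-10):
            raise ValueError("eigenvalues must be nonnegative (up to roundoff)")
        if np.any(np.diff(ev) > 1e-10):
            raise ValueError("eigenvalues must be nonincreasing")
        self.eigenvalues = np.maximum(ev, 0.0)

    @property
    def grid(self) -> FrequencyGrid:
        return self.mean_function.grid

    @property
    def n_components(self) -> int:
        return len(self.eigenfunctions)

    def eigenfunction_matrix(self) -> np.ndarray:
        return stack_values(self.eigenfunctions)


def subset_by_state(
    dataset: Sequence[FunctionalSeries],
    paths: Sequence[ViterbiPath],
    state: int,
) -> list[Curve]:
    """Curves whose decoded latent state equals ``state``.

    Paths are matched to series by individual id and must cover each
    series observation-for-observation.
    """
    by_id = {p.individual_id: p for p in paths}
    out: list[Curve] = []
    for series in dataset:
        path = by_id.get(series.individual_id)
        if path is None:
            raise ValueError(f"no decoded path for individual {series.individual_id!r}")
        if len(path) != len(series):
            raise ValueError(
                f"path length {len(path)} != series length {len(series)} "
                f"for individual {series.individual_id!r}"
            )
        for curve, s in zip(series.curves, path.states):
            if s == state:
                out.append(curve)
    return out


def fit_fpca(
    curves: Sequence[Curve],
    basis: BasisSystem | None = None,
    penalty: float = DEFAULT_PENALTY,
    n_components: int | str = "all",
    state_label: Hashable = None,
) -> FPCAModel:
    """Fit an FPCA model to a set of curves.

    Each curve is represented by its penalised B-spline smooth; the
    mean of the smoothed curves is the mean function, and the
    eigenproblem of their covariance (in the quadrature metric) gives
    L2-orthonormal eigenfunctions with nonincreasing eigenvalues.
    Scores are quadrature inner products of the raw centered curves
    with the eigenfunctions; ``variance_fractions`` are eigenvalues
    over their total.
    """
    if len(curves) < 2:
        raise ValueError("FPCA needs at least 2 curves")
    Y = stack_values(curves)
    grid = curves[0].grid
    if basis is None:
        basis = BasisSystem.for_grid(grid)
    B = basis.design_matrix(grid.points)

    coefs = _solve_penalised(B, basis.penalty_matrix, penalty, Y.T).T  # (n, m)
    mean_coef = coefs.mean(axis=0)
    mean_vals = B @ mean_coef

    w = fpca_weights(grid)
    sw = np.sqrt(w)
    smooth_centered = (coefs - mean_coef) @ B.T
    n = Y.shape[0]
    _, svals, Vt = np.linalg.svd(smooth_centered * sw, full_matrices=False)
    eigvals = svals**2 / (n - 1)
    phi = Vt / sw  # rows orthonormal under the quadrature metric

    # deterministic sign: largest-magnitude value of each mode positive
    flips = np.sign(phi[np.arange(phi.shape[0]), np.argmax(np.abs(phi), axis=1)])
    flips[flips == 0] = 1.0
    phi = phi * flips[:, None]

    total = eigvals.sum()
    if total > 0:
        fractions = eigvals / total
    else:  # degenerate: all curves identical
        fractions = np.zeros_like(eigvals)

    if n_components != "all":
        ncomp = int(n_components)
        if ncomp < 1:
            raise ValueError("n_components must be positive")
        ncomp = min(ncomp, phi.shape[0])
    else:
        ncomp = phi.shape[0]

    scores = ((Y - mean_vals) * w) @ phi[:ncomp].T
    return FPCAModel(
        state_label=state_label,
        mean_function=Curve(grid, mean_vals),
        eigenfunctions=[Curve(grid, phi[c]) for c in range(ncomp)],
        eigenvalues=eigvals[:ncomp],
        scores=scores,
        variance_fractions=fractions,
        n_retained=ncomp,
        basis=basis,
        penalty=penalty,
        obs_ids=[(c.individual_id, c.time_index) for c in curves],
    )


def choose_n_components(
    variance_fractions: Sequence[float],
    threshold: float = RETENTION_THRESHOLD,
) -> int:
    """Smallest number of leading components whose cumulative variance
    share strictly exceeds ``threshold``.

    Falls back (with a warning) to all components if the cumulative
    share never exceeds the threshold.
    """
    fractions = np.asarray(variance_fractions, float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("variance fractions must lie in [0, 1]")
    cumulative = np.cumsum(fractions)
    above = np.nonzero(cumulative > threshold)[0]
    if above.size == 0:
        warnings.warn(
            f"cumulative variance never exceeds {threshold}; retaining all "
            f"{fractions.size} components",
            RuntimeWarning,
            stacklevel=2,
        )
        return int(fractions.size)
    return int(above[0]) + 1


def scree_data(variance_fractions: Sequence[float]) -> pd.DataFrame:
    """Per-component and cumulative variance shares for a scree plot."""
    fractions = np.asarray(variance_fractions, float)
    return pd.DataFrame(
        {
            "component": np.arange(1, fractions.size + 1),
            "variance_fraction": fractions,
            "cumulative": np.cumsum(fractions),
        }
    )


def project_scores(model: FPCAModel, curves: Sequence[Curve]) -> np.ndarray:
    """Scores of curves on the model's retained eigenfunctions.

    Quadrature inner product of (curve - mean function) with each
    eigenfunction; applied to the training curves this reproduces the
    stored scores.
    """
    Y = stack_values(curves)
    if curves[0].grid != model.grid:
        raise ValueError("curves are not on the model grid")
    w = fpca_weights(model.grid)
    phi = model.eigenfunction_matrix()
    return ((Y - model.mean_function.values) * w) @ phi.T


def individual_mean_scores(
    model: FPCAModel,
    provenance: Mapping[int, Hashable] | None = None,
    n_components: int = 5,
) -> pd.DataFrame:
    """Per-individual mean of observation-level scores.

    ``provenance`` maps observation index to individual id; defaults
    to the ids recorded at fit time.  Only individuals with at least
    one observation in the curve set appear.  Columns are
    ``fpc_score_1..n`` for the first ``n_components`` retained
    components (capped at what the model holds).
    """
    n_obs = model.scores.shape[0]
    if provenance is None:
        provenance = {i: model.obs_ids[i][0] for i in range(n_obs)}
    missing = [i for i in range(n_obs) if i not in provenance]
    if missing:
        raise ValueError(f"observations without an individual mapping: {missing[:5]}")
    ncomp = min(n_components, model.scores.shape[1])
    frame = pd.DataFrame(
        model.scores[:, :ncomp],
        columns=[f"fpc_score_{c + 1}" for c in range(ncomp)],
    )
    frame["individual_id"] = [provenance[i] for i in range(n_obs)]
    out = frame.groupby("individual_id", sort=True).mean()
    return out
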