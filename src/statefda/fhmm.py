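"""Functional hidden Markov model with distance-based emissions.

The latent process is an ordinary first-order Markov chain on a finite
state space; each state ``i`` carries a centroid curve ``mu_i`` and
emits an observed curve ``x`` with pseudo-likelihood

    b_i(x) = h(d(x, mu_i)),    h(y) = 1 / (y^2 + eps),

where ``d`` is the L2 distance between curves (trapezoidal quadrature)
and ``eps`` is a small regulariser that keeps the similarity finite
when a curve coincides with a centroid.  The emissions are similarity
weights rather than normalised densities, so all likelihood-like
quantities in this module are *pseudo*-likelihoods; the scaled
forward--backward recursions, Baum--Welch EM and Viterbi decoding
otherwise follow the standard HMM constructions.

Initialisation follows a subsampling consensus strategy: many models
with a deliberately generous state count are fit on random subsamples
of individuals, their centroids are pooled, grouped by average-linkage
clustering (or manually), and group means become the initial centroids
of the final model.  This guards against the tendency of randomly
initialised functional k-means to collapse several states onto one
centroid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Literal, Mapping, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

from .core import (
    Curve,
    FrequencyGrid,
    FunctionalSeries,
    stack_values,
    trapezoid_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FHMMModel",
    "ForwardBackwardResult",
    "ViterbiPath",
    "CentroidPool",
    "CentroidGrouping",
    "FitHistory",
    "l2_distance",
    "emission",
    "forward_backward",
    "baum_welch",
    "viterbi",
    "functional_kmeans",
    "subsample_initialise",
    "group_centroids",
    "relabel_states",
    "make_initial_model",
    "split_by_segments",
]

#: Emission regularisation, as a fraction of the grid range.
EPSILON_SCALE = 1e-12

#: Total responsibility below which a state is declared degenerate and
#: its centroid frozen for the remainder of the fit.
DEGENERATE_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# model container


@dataclass
class FHMMModel:
    """A fitted or hand-built functional HMM.

    ``initial_distribution`` (nu) and each row of ``transition_matrix``
    (A) must be probability vectors; ``centroids`` share one grid.
    """

    n_states: int
    initial_distribution: np.ndarray
    transition_matrix: np.ndarray
    centroids: list[Curve]
    emission_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.initial_distribution = np.asarray(self.initial_distribution, float)
        self.transition_matrix = np.asarray(self.transition_matrix, float)
        if self.emission_epsilon is None:
            self.emission_epsilon = EPSILON_SCALE * self.grid.range
        self.validate()

    @property
    def grid(self) -> FrequencyGrid:
        return self.centroids[0].grid

    def centroid_matrix(self) -> np.ndarray:
        """(N, G) matrix of stacked centroid values."""
        return stack_values(self.centroids)

    def validate(self) -> None:
        N = self.n_states
        nu, A = self.initial_distribution, self.transition_matrix
        if nu.shape != (N,) or A.shape != (N, N):
            raise ValueError("nu / A shapes inconsistent with n_states")
        if np.any(nu < -1e-12) or abs(nu.sum() - 1.0) > 1e-10:
            raise ValueError("initial distribution must be a probability vector")
        if np.any(A < -1e-12) or np.any(np.abs(A.sum(axis=1) - 1.0) > 1e-10):
            raise ValueError("each transition-matrix row must sum to 1")
        if len(self.centroids) != N:
            raise ValueError("need one centroid per state")
        grid = self.grid
        if any(c.grid != grid for c in self.centroids):
            raise ValueError("centroids must share one grid")
        if self.emission_epsilon <= 0:
            raise ValueError("emission_epsilon must be positive")

    def copy(self) -> "FHMMModel":
        return FHMMModel(
            self.n_states,
            self.initial_distribution.copy(),
            self.transition_matrix.copy(),
            [c.copy() for c in self.centroids],
            emission_epsilon=self.emission_epsilon,
        )


@dataclass
class ForwardBackwardResult:
    log_pseudo_likelihood: float
    gamma: np.ndarray  # (K, N)
    xi: np.ndarray  # (K-1, N, N)
    scaling_factors: np.ndarray  # (K,)


@dataclass
class ViterbiPath:
    individual_id: Hashable
    states: np.ndarray  # (K,) labels in 1..N
    path_log_score: float

    def __len__(self) -> int:
        return self.states.size


@dataclass
class FitHistory:
    """Objective trace and bookkeeping of one Baum--Welch run."""

    objective: list[float] = field(default_factory=list)
    converged: bool = False
    n_iter: int = 0
    degenerate_states: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# distances and emissions


def l2_distance(x: Curve, mu: Curve) -> float:
    """L2 distance between two curves by trapezoidal quadrature."""
    if x.grid != mu.grid:
        raise ValueError("curves are defined on different grids")
    w = trapezoid_weights(x.grid)
    diff = x.values - mu.values
    return float(np.sqrt(np.sum(w * diff * diff)))


def emission(x: Curve, mu: Curve, epsilon: float) -> float:
    """Distance-based emission pseudo-likelihood 1 / (d^2 + epsilon)."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    d = l2_distance(x, mu)
    return 1.0 / (d * d + epsilon)


def _sq_distances(values: np.ndarray, centroids: np.ndarray, w: np.ndarray) -> np.ndarray:
    """(n, N) squared weighted-L2 distances between rows of ``values``
    and rows of ``centroids``."""
    xw = values * w
    d2 = (
        (values * xw).sum(axis=1)[:, None]
        - 2.0 * xw @ centroids.T
        + ((centroids * centroids) * w).sum(axis=1)[None, :]
    )
    return np.maximum(d2, 0.0)


def _emission_matrix(
    values: np.ndarray, model: FHMMModel, w: np.ndarray
) -> np.ndarray:
    d2 = _sq_distances(values, model.centroid_matrix(), w)
    return 1.0 / (d2 + model.emission_epsilon)


# ---------------------------------------------------------------------------
# forward--backward (scaled), batched over sequences of equal length


def _forward_backward_batched(
    B: np.ndarray, nu: np.ndarray, A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled recursions for a batch of sequences.

    Parameters
    ----------
    B : (S, K, N) emission pseudo-likelihoods.

    Returns
    -------
    gamma : (S, K, N), xi : (S, K-1, N, N), scale : (S, K)
    """
    S, K, N = B.shape
    alpha = np.empty((S, K, N))
    scale = np.empty((S, K))

    a = nu[None, :] * B[:, 0, :]
    c = a.sum(axis=1)
    if np.any(c <= 0.0):
        raise FloatingPointError("all emissions vanished at the first step")
    alpha[:, 0] = a / c[:, None]
    scale[:, 0] = c
    for k in range(1, K):
        a = (alpha[:, k - 1] @ A) * B[:, k]
        c = a.sum(axis=1)
        if np.any(c <= 0.0):
            raise FloatingPointError(f"all emissions vanished at step {k}")
        alpha[:, k] = a / c[:, None]
        scale[:, k] = c

    beta = np.empty((S, K, N))
    beta[:, K - 1] = 1.0
    for k in range(K - 2, -1, -1):
        beta[:, k] = (B[:, k + 1] * beta[:, k + 1]) @ A.T / scale[:, k + 1, None]

    gamma = alpha * beta
    gamma /= gamma.sum(axis=2, keepdims=True)

    xi = np.empty((S, max(K - 1, 0), N, N))
    for k in range(K - 1):
        m = (
            alpha[:, k, :, None]
            * A[None, :, :]
            * (B[:, k + 1] * beta[:, k + 1])[:, None, :]
            / scale[:, k + 1, None, None]
        )
        xi[:, k] = m / m.sum(axis=(1, 2), keepdims=True)
    return gamma, xi, scale


def forward_backward(series: FunctionalSeries, model: FHMMModel) -> ForwardBackwardResult:
    """Posterior state probabilities and log pseudo-likelihood.

    Returns the smoothed marginals gamma_k(i), the pairwise marginals
    xi_k(i, j), and ``log_pseudo_likelihood = sum(log scaling_factors)``.
    """
    model.validate()
    w = trapezoid_weights(series.grid)
    B = _emission_matrix(series.values, model, w)[None]
    gamma, xi, scale = _forward_backward_batched(
        B, model.initial_distribution, model.transition_matrix
    )
    return ForwardBackwardResult(
        log_pseudo_likelihood=float(np.log(scale[0]).sum()),
        gamma=gamma[0],
        xi=xi[0],
        scaling_factors=scale[0],
    )


# ---------------------------------------------------------------------------
# Baum--Welch over multiple sequences


def baum_welch(
    dataset: Sequence[FunctionalSeries],
    init: FHMMModel,
    tol: float = 1e-6,
    max_iter: int = 200,
    centroid_update: Literal["mm", "mean"] = "mm",
) -> tuple[FHMMModel, FitHistory]:
    """Fit one shared model to multiple curve sequences by EM.

    E-step: forward--backward per sequence under the current model.
    M-step: nu is the average of gamma_1 across sequences; each
    transition row is the pooled sum of xi over sequences and time,
    normalised; centroids are responsibility-weighted pointwise means
    of all observed curves.

    With ``centroid_update="mm"`` (default) the responsibilities are
    additionally weighted by 1/(d^2 + eps) to the current centroid — a
    majorisation step for the log-emission term that makes the EM
    objective provably nondecreasing under the 1/(d^2+eps) emission
    model.  ``"mean"`` uses the plain gamma-weighted mean (the
    minimiser of the gamma-weighted squared L2 distance), which is the
    k-means-style update but carries no monotonicity guarantee.

    Stops when the relative change of the total log pseudo-likelihood
    falls below ``tol``, or after ``max_iter`` iterations.  States
    whose total responsibility falls below a small floor are flagged
    degenerate and their centroids frozen.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    init.validate()
    grid = init.grid
    if any(s.grid != grid for s in dataset):
        raise ValueError("all series must share the model grid")
    w = trapezoid_weights(grid)
    N = init.n_states
    eps = init.emission_epsilon

    # group series by length so recursions run batched
    by_len: dict[int, list[int]] = {}
    for idx, s in enumerate(dataset):
        by_len.setdefault(len(s), []).append(idx)
    values = {L: np.stack([dataset[i].values for i in idxs]) for L, idxs in by_len.items()}

    nu = init.initial_distribution.copy()
    A = init.transition_matrix.copy()
    M = init.centroid_matrix().copy()
    history = FitHistory()
    frozen = np.zeros(N, dtype=bool)
    prev_ll = -np.inf

    for it in range(max_iter):
        ll = 0.0
        nu_acc = np.zeros(N)
        xi_acc = np.zeros((N, N))
        gam_acc = np.zeros(N)
        num_acc = np.zeros((N, M.shape[1]))
        den_acc = np.zeros(N)
        n_series = 0
        for L, X in values.items():
            S = X.shape[0]
            B = 1.0 / (_sq_distances(X.reshape(S * L, -1), M, w).reshape(S, L, N) + eps)
            gamma, xi, scale = _forward_backward_batched(B, nu, A)
            ll += float(np.log(scale).sum())
            nu_acc += gamma[:, 0].sum(axis=0)
            if L > 1:
                xi_acc += xi.sum(axis=(0, 1))
            g_flat = gamma.reshape(S * L, N)
            gam_acc += g_flat.sum(axis=0)
            if centroid_update == "mm":
                wts = g_flat * B.reshape(S * L, N)  # gamma / (d^2 + eps)
            else:
                wts = g_flat
            num_acc += wts.T @ X.reshape(S * L, -1)
            den_acc += wts.sum(axis=0)
            n_series += S
        history.objective.append(ll)

        if it > 0 and ll - prev_ll < tol * max(1.0, abs(prev_ll)):
            history.converged = True
            break
        prev_ll = ll

        # M-step
        nu = nu_acc / n_series
        nu = np.maximum(nu, 0.0)
        nu /= nu.sum()
        row = xi_acc.sum(axis=1)
        A_new = np.where(row[:, None] > 0, xi_acc / np.maximum(row[:, None], 1e-300), A)
        A = A_new / A_new.sum(axis=1, keepdims=True)

        newly_degenerate = (gam_acc < DEGENERATE_FLOOR) & ~frozen
        for i in np.nonzero(newly_degenerate)[0]:
            warnings.warn(
                f"state {i + 1} received ~zero responsibility; centroid frozen",
                RuntimeWarning,
                stacklevel=2,
            )
            history.degenerate_states.append(int(i + 1))
        frozen |= newly_degenerate
        upd = (~frozen) & (den_acc > 0)
        M[upd] = num_acc[upd] / den_acc[upd, None]

    history.n_iter = len(history.objective)
    model = FHMMModel(
        n_states=N,
        initial_distribution=nu,
        transition_matrix=A,
        centroids=[Curve(grid, M[i].copy()) for i in range(N)],
        emission_epsilon=eps,
    )
    return model, history


# ---------------------------------------------------------------------------
# Viterbi decoding


def viterbi(series: FunctionalSeries, model: FHMMModel) -> ViterbiPath:
    """Maximum a posteriori state path by dynamic programming in log
    space.  Ties are broken toward the lowest state index, so decoding
    is deterministic."""
    model.validate()
    w = trapezoid_weights(series.grid)
    logB = np.log(_emission_matrix(series.values, model, w))
    with np.errstate(divide="ignore"):
        log_nu = np.log(model.initial_distribution)
        log_A = np.log(model.transition_matrix)
    K, N = logB.shape
    delta = np.empty((K, N))
    back = np.zeros((K, N), dtype=int)
    delta[0] = log_nu + logB[0]
    for k in range(1, K):
        cand = delta[k - 1][:, None] + log_A  # (from, to)
        back[k] = np.argmax(cand, axis=0)  # argmax -> lowest index on ties
        delta[k] = cand[back[k], np.arange(N)] + logB[k]
    states = np.empty(K, dtype=int)
    states[K - 1] = int(np.argmax(delta[K - 1]))
    for k in range(K - 2, -1, -1):
        states[k] = back[k + 1][states[k + 1]]
    score = log_nu[states[0]] + logB[0, states[0]]
    for k in range(1, K):
        score += log_A[states[k - 1], states[k]] + logB[k, states[k]]
    return ViterbiPath(
        individual_id=series.individual_id,
        states=states + 1,
        path_log_score=float(score),
    )


# ---------------------------------------------------------------------------
# functional k-means and the subsampling consensus initialisation


def functional_kmeans(
    curves: Sequence[Curve],
    k: int,
    seed: int,
    n_restarts: int = 10,
) -> list[Curve]:
    """Lloyd k-means under the trapezoid-weighted L2 curve distance.

    Initial centroids are drawn uniformly without replacement from the
    curves; the best of ``n_restarts`` runs by within-cluster sum of
    squared L2 distances is kept.  Implemented by scaling each grid
    column by the square root of its quadrature weight, which turns the
    functional distance into plain Euclidean distance.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(curves):
        raise ValueError(f"k={k} exceeds the number of curves ({len(curves)})")
    X = stack_values(curves)
    grid = curves[0].grid
    sw = np.sqrt(trapezoid_weights(grid))
    km = KMeans(
        n_clusters=k,
        init="random",
        n_init=n_restarts,
        random_state=seed % (2**32),
        algorithm="lloyd",
    ).fit(X * sw)
    centroids = km.cluster_centers_ / sw
    return [Curve(grid, centroids[i]) for i in range(k)]


def make_initial_model(
    centroids: Sequence[Curve],
    self_transition: float = 0.9,
    emission_epsilon: float | None = None,
) -> FHMMModel:
    """Build a starting model around given centroids: uniform nu and a
    sticky transition matrix with the given self-transition mass."""
    N = len(centroids)
    if not 0 < self_transition <= 1:
        raise ValueError("self_transition must be in (0, 1]")
    if N == 1:
        A = np.ones((1, 1))
    else:
        off = (1.0 - self_transition) / (N - 1)
        A = np.full((N, N), off)
        np.fill_diagonal(A, self_transition)
    return FHMMModel(
        n_states=N,
        initial_distribution=np.full(N, 1.0 / N),
        transition_matrix=A,
        centroids=[c.copy() for c in centroids],
        emission_epsilon=emission_epsilon,
    )


@dataclass
class CentroidPool:
    """Centroids pooled across subsampled model fits, with provenance."""

    centroids: list[Curve]
    provenance: list[tuple[int, int]]  # (model index, state index), 1-based

    def __len__(self) -> int:
        return len(self.centroids)


def subsample_initialise(
    dataset: Sequence[FunctionalSeries],
    n_models: int = 10,
    subsample_fraction: float = 0.8,
    states_per_model: int = 8,
    seed: int = 0,
    baum_welch_kwargs: Mapping | None = None,
) -> CentroidPool:
    """Fit many generously sized models on random subsamples of the
    individuals and pool their centroids.

    Each of ``n_models`` fits draws ``floor(fraction * P)`` individuals
    without replacement, initialises with functional k-means on the
    subsample's curves, and runs Baum--Welch with ``states_per_model``
    states.  The pooled centroids (with model/state provenance) feed
    :func:`group_centroids`.
    """
    if not 0.0 < subsample_fraction < 1.0:
        raise ValueError("subsample_fraction must be in (0, 1)")
    P = len(dataset)
    needed = int(np.ceil(1.0 / (1.0 - subsample_fraction)))
    if P < needed:
        raise ValueError(
            f"need at least {needed} individuals for subsample_fraction="
            f"{subsample_fraction} (got {P})"
        )
    n_sub = int(np.floor(subsample_fraction * P))
    bw_kwargs = dict(baum_welch_kwargs or {})
    children = np.random.SeedSequence(seed).spawn(n_models)
    pool = CentroidPool(centroids=[], provenance=[])
    for m, child in enumerate(children, start=1):
        rng = np.random.default_rng(child)
        chosen = rng.choice(P, size=n_sub, replace=False)
        sub = [dataset[i] for i in chosen]
        curves = [c for s in sub for c in s.curves]
        km_seed = int(rng.integers(2**31 - 1))
        init_centroids = functional_kmeans(curves, states_per_model, seed=km_seed)
        init = make_initial_model(init_centroids)
        model, hist = baum_welch(sub, init, **bw_kwargs)
        logger.info(
            "subsample model %d/%d: %d iterations, objective %.3f",
            m, n_models, hist.n_iter, hist.objective[-1],
        )
        for i, c in enumerate(model.centroids, start=1):
            pool.centroids.append(c)
            pool.provenance.append((m, i))
    return pool


@dataclass
class CentroidGrouping:
    """Result of grouping a centroid pool into initial states."""

    labels: np.ndarray  # group label per pool member, 1..n_groups
    groups: dict[int, list[int]]  # group label -> pool indices
    initial_centroids: list[Curve]  # one per group, pointwise mean
    distance_matrix: np.ndarray  # pairwise L2 distances in the pool


def group_centroids(
    pool: CentroidPool,
    method: Literal["agglomerative", "manual"] = "agglomerative",
    n_groups: int | None = None,
    distance_threshold: float | None = None,
    manual_labels: Mapping[int, int] | None = None,
) -> CentroidGrouping:
    """Group pooled centroids and average each group into one initial
    centroid.

    Agglomerative mode clusters the pool by average linkage on pairwise
    L2 distances, cut either at ``n_groups`` clusters or at
    ``distance_threshold``.  Manual mode applies user-supplied labels
    verbatim (mirroring the visual heuristic grouping of overlaid
    centroid plots).  Exactly one of the three selectors must be given.
    """
    selectors = [n_groups is not None, distance_threshold is not None,
                 manual_labels is not None]
    if sum(selectors) != 1:
        raise ValueError(
            "supply exactly one of n_groups, distance_threshold, manual_labels"
        )
    n_pool = len(pool)
    X = stack_values(pool.centroids)
    w = trapezoid_weights(pool.centroids[0].grid)
    D = np.sqrt(_sq_distances(X, X, w))
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)

    if method == "manual":
        if manual_labels is None:
            raise ValueError("manual method requires manual_labels")
        missing = set(range(n_pool)) - set(manual_labels)
        if missing:
            raise ValueError(f"manual_labels do not cover pool indices {sorted(missing)}")
        uniq = sorted(set(manual_labels.values()))
        relabel = {g: i + 1 for i, g in enumerate(uniq)}
        labels = np.array([relabel[manual_labels[i]] for i in range(n_pool)])
    elif method == "agglomerative":
        if manual_labels is not None:
            raise ValueError("manual_labels only valid with method='manual'")
        if n_pool == 1:
            labels = np.array([1])
        else:
            Z = linkage(squareform(D, checks=False), method="average")
            if n_groups is not None:
                labels = fcluster(Z, t=n_groups, criterion="maxclust")
            else:
                labels = fcluster(Z, t=distance_threshold, criterion="distance")
    else:
        raise ValueError(f"unknown method {method!r}")

    groups: dict[int, list[int]] = {}
    for i, g in enumerate(labels):
        groups.setdefault(int(g), []).append(i)
    if any(len(v) == 0 for v in groups.values()) or not groups:
        raise ValueError("grouping produced an empty group")
    grid = pool.centroids[0].grid
    initial = [
        Curve(grid, X[groups[g]].mean(axis=0)) for g in sorted(groups)
    ]
    return CentroidGrouping(
        labels=np.asarray(labels, int),
        groups={g: groups[g] for g in sorted(groups)},
        initial_centroids=initial,
        distance_matrix=D,
    )


# ---------------------------------------------------------------------------
# relabelling and segment handling


def relabel_states(
    model: FHMMModel, paths: Sequence[ViterbiPath]
) -> tuple[FHMMModel, list[ViterbiPath]]:
    """Reorder state labels by decreasing allocation frequency.

    State 1 becomes the state with the most decoded observations, ties
    broken toward the lower original index; nu, A, centroids and all
    paths are permuted consistently.
    """
    N = model.n_states
    counts = np.zeros(N, dtype=int)
    for p in paths:
        counts += np.bincount(p.states - 1, minlength=N)
    order = np.array(sorted(range(N), key=lambda i: (-counts[i], i)))
    inv = np.empty(N, dtype=int)
    inv[order] = np.arange(N)
    new_model = FHMMModel(
        n_states=N,
        initial_distribution=model.initial_distribution[order],
        transition_matrix=model.transition_matrix[np.ix_(order, order)],
        centroids=[model.centroids[i].copy() for i in order],
        emission_epsilon=model.emission_epsilon,
    )
    new_paths = [
        ViterbiPath(p.individual_id, inv[p.states - 1] + 1, p.path_log_score)
        for p in paths
    ]
    return new_model, new_paths


def split_by_segments(series: FunctionalSeries) -> list[FunctionalSeries]:
    """Split a series into one sub-series per contiguous segment_id run.

    Used when the Markov chain should restart (with nu) at segment
    boundaries — e.g. eyes-closed blocks separated by eyes-open gaps —
    instead of transitioning across the gap.
    """
    out: list[list[Curve]] = []
    current_seg: Hashable = object()
    for c in series.curves:
        if not out or c.segment_id != current_seg:
            out.append([])
            current_seg = c.segment_id
        out[-1].append(c)
    return [FunctionalSeries(series.individual_id, chunk) for chunk in out]
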