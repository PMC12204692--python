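"""Curve preparation: penalised B-spline smoothing and spectral
parameterisation of power spectra.

The spectral parameteriser separates a log10-power spectrum into an
aperiodic 1/f background, ``offset - exponent * log10(f)``, and a sum
of Gaussian oscillatory peaks.  The peak-only reconstruction (periodic
content with the aperiodic background removed) is the curve the
functional HMM consumes.  This is a self-contained implementation of
the spectral "peaks over 1/f" decomposition with the conventional
settings for band-limited EEG spectra: peak full-widths limited to
1--12 Hz, no cap on the number of peaks, minimum peak height 0.05,
relative peak threshold 2 standard deviations, aperiodic mode fixed
(no knee).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import least_squares

from .core import Curve, FrequencyGrid

logger = logging.getLogger(__name__)

__all__ = [
    "BasisSystem",
    "bspline_smooth",
    "SpectralSettings",
    "SpectralFit",
    "fit_spectral_model",
    "peak_curve",
    "gaussian_sum",
]


# ---------------------------------------------------------------------------
# B-spline basis


def _gauss_legendre_nodes(breaks: np.ndarray, q: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on each break interval, flattened."""
    x, w = np.polynomial.legendre.leggauss(q)
    a, b = breaks[:-1], breaks[1:]
    half = (b - a) / 2.0
    nodes = (a[:, None] + half[:, None] * (x[None, :] + 1.0)).ravel()
    weights = (half[:, None] * w[None, :]).ravel()
    return nodes, weights


@dataclass
class BasisSystem:
    """B-spline basis with exact Gram and curvature-penalty matrices.

    ``order`` is the polynomial order (4 = cubic).  ``knots`` is the
    full knot vector with ``order``-fold endpoint repeats.  The Gram
    matrix holds pairwise L2 inner products of the basis functions and
    the penalty matrix their second-derivative inner products, both
    evaluated exactly by Gauss-Legendre quadrature per knot interval.
    """

    order: int
    knots: np.ndarray
    gram_matrix: np.ndarray = field(init=False, repr=False)
    penalty_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.knots = np.asarray(self.knots, float)
        if self.order < 2:
            raise ValueError("order must be at least 2")
        k = self.order - 1
        breaks = np.unique(self.knots)
        nodes, wq = _gauss_legendre_nodes(breaks, q=self.order)
        D = BSpline.design_matrix(nodes, self.knots, k).toarray()
        self.gram_matrix = (D * wq[:, None]).T @ D
        coefs = np.eye(self.n_basis)
        spl = BSpline(self.knots, coefs, k)
        D2 = spl.derivative(2)(nodes)  # (n_nodes, n_basis)
        self.penalty_matrix = (D2 * wq[:, None]).T @ D2

    @property
    def n_basis(self) -> int:
        return self.knots.size - self.order

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.knots[0]), float(self.knots[-1])

    def design_matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, float)
        lo, hi = self.domain
        if x.min() < lo or x.max() > hi:
            raise ValueError("evaluation points fall outside the knot range")
        return BSpline.design_matrix(x, self.knots, self.order - 1).toarray()

    @classmethod
    def for_grid(
        cls,
        grid: FrequencyGrid,
        n_basis: int | None = None,
        order: int = 4,
    ) -> "BasisSystem":
        """Basis spanning a grid.

        By default the breakpoints sit at every other grid point.  Pass
        ``n_basis = len(grid)`` for a saturated (interpolating) basis.
        """
        lo, hi = float(grid.points[0]), float(grid.points[-1])
        if n_basis is None:
            breaks = np.unique(np.append(grid.points[::2], hi))
        else:
            n_break = n_basis - order + 2
            if n_break < 2:
                raise ValueError(f"n_basis={n_basis} too small for order {order}")
            breaks = np.linspace(lo, hi, n_break)
        knots = np.concatenate(
            [np.repeat(breaks[0], order - 1), breaks, np.repeat(breaks[-1], order - 1)]
        )
        return cls(order=order, knots=knots)


def bspline_smooth(
    curve: Curve,
    basis: BasisSystem,
    penalty: float = 0.0,
) -> tuple[np.ndarray, Curve]:
    """Penalised least-squares spline fit of one curve.

    Minimises ``||y - B c||^2 + penalty * c' P c`` where ``P`` is the
    second-derivative penalty matrix; returns the coefficient vector
    and the smoothed curve on the input grid.
    """
    if penalty < 0:
        raise ValueError("penalty must be nonnegative")
    B = basis.design_matrix(curve.grid.points)
    coef = _solve_penalised(B, basis.penalty_matrix, penalty, curve.values[:, None])
    smoothed = Curve(
        curve.grid,
        B @ coef[:, 0],
        individual_id=curve.individual_id,
        time_index=curve.time_index,
        segment_id=curve.segment_id,
    )
    return coef[:, 0], smoothed


def _solve_penalised(
    B: np.ndarray, P: np.ndarray, penalty: float, Y: np.ndarray
) -> np.ndarray:
    """Solve (B'B + penalty P) C = B'Y for possibly many right-hand sides."""
    lhs = B.T @ B + penalty * P
    try:
        c, low = cho_factor(lhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular normal equations: too many basis functions for the "
            "grid at this penalty"
        ) from exc
    return cho_solve((c, low), B.T @ Y)


# ---------------------------------------------------------------------------
# spectral parameterisation


def gaussian_sum(
    points: np.ndarray, peaks: Sequence[tuple[float, float, float]]
) -> np.ndarray:
    """Pointwise sum of Gaussians given as (center, amplitude, sd)."""
    out = np.zeros(np.shape(points), dtype=float)
    for center, amp, sd in peaks:
        out = out + amp * np.exp(-0.5 * ((points - center) / sd) ** 2)
    return out


@dataclass(frozen=True)
class SpectralSettings:
    """Settings of the spectral parameteriser.

    ``peak_width_limits`` bound the full width (2 sd) of a Gaussian
    peak in Hz, so the sd is constrained to half these limits.
    ``min_peak_height`` is an absolute floor (log10 power) and
    ``peak_threshold`` a relative floor in residual standard
    deviations; peak extraction stops when the tallest residual point
    falls below both.  ``robust_tail`` is the upper-tail fraction of
    residuals dropped when refitting the aperiodic component.
    """

    peak_width_limits: tuple[float, float] = (1.0, 12.0)
    max_peaks: int | None = None
    min_peak_height: float = 0.05
    peak_threshold: float = 2.0
    fit_range: tuple[float, float] = (1.5, 30.0)
    robust_tail: float = 0.025
    refit_rounds: int = 2

    @property
    def sd_limits(self) -> tuple[float, float]:
        return self.peak_width_limits[0] / 2.0, self.peak_width_limits[1] / 2.0


@dataclass
class SpectralFit:
    """Aperiodic + Gaussian-peak decomposition of one spectrum."""

    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]  # (center Hz, amplitude, sd Hz)
    fit_range: tuple[float, float]
    r_squared: float
    peak_curve: Curve
    settings: SpectralSettings = field(default_factory=SpectralSettings)

    def __post_init__(self) -> None:
        lo, hi = self.fit_range
        sd_lo, sd_hi = self.settings.sd_limits
        for center, amp, sd in self.peaks:
            if not lo <= center <= hi:
                raise ValueError(f"peak center {center} outside fit range")
            if amp < self.settings.min_peak_height - 1e-12:
                raise ValueError(f"peak amplitude {amp} below the minimum height")
            if not sd_lo - 1e-9 <= sd <= sd_hi + 1e-9:
                raise ValueError(f"peak sd {sd} outside the width limits")
        expected = gaussian_sum(self.peak_curve.grid.points, self.peaks)
        if not np.allclose(self.peak_curve.values, expected, atol=1e-10):
            raise ValueError("peak_curve inconsistent with the peak list")

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        return self.offset - self.exponent * np.log10(freqs)

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic(freqs) + gaussian_sum(freqs, self.peaks)


def _aperiodic_fit(freqs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares fit of y = offset - exponent * log10(f)."""
    X = np.column_stack([np.ones_like(freqs), -np.log10(freqs)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(beta[0]), float(beta[1])


def _robust_aperiodic_fit(
    freqs: np.ndarray, y: np.ndarray, tail: float
) -> tuple[float, float]:
    """Aperiodic fit that drops the upper residual tail (peak regions
    bias a plain fit upward) and refits."""
    offset, exponent = _aperiodic_fit(freqs, y)
    resid = y - (offset - exponent * np.log10(freqs))
    thresh = np.quantile(resid, 1.0 - tail)
    keep = resid <= thresh
    if keep.sum() >= 2:
        offset, exponent = _aperiodic_fit(freqs[keep], y[keep])
    return offset, exponent


_HALF_WIDTH_TO_SD = 1.0 / np.sqrt(2.0 * np.log(2.0))  # half-width at half max


def _guess_sd(freqs: np.ndarray, resid: np.ndarray, idx: int, height: float,
              sd_limits: tuple[float, float]) -> float:
    half = height / 2.0
    li = idx
    while li > 0 and resid[li - 1] > half:
        li -= 1
    ri = idx
    while ri < resid.size - 1 and resid[ri + 1] > half:
        ri += 1
    spans = []
    if li > 0 or resid[li] <= half:
        spans.append(freqs[idx] - freqs[li])
    if ri < resid.size - 1 or resid[ri] <= half:
        spans.append(freqs[ri] - freqs[idx])
    hwhm = np.mean(spans) if spans else (sd_limits[0] + sd_limits[1]) / 2.0
    sd = max(hwhm, 1e-3) * _HALF_WIDTH_TO_SD
    return float(np.clip(sd, *sd_limits))


def _extract_peaks(
    freqs: np.ndarray, flat: np.ndarray, settings: SpectralSettings
) -> list[tuple[float, float, float]]:
    """Iteratively find-and-subtract Gaussian peak guesses from the
    aperiodic-subtracted spectrum."""
    resid = flat.copy()
    guesses: list[tuple[float, float, float]] = []
    max_peaks = settings.max_peaks if settings.max_peaks is not None else 100
    while len(guesses) < max_peaks:
        idx = int(np.argmax(resid))
        height = resid[idx]
        stop_level = max(
            settings.min_peak_height,
            settings.peak_threshold * float(np.std(resid)),
        )
        if height < stop_level:
            break
        sd = _guess_sd(freqs, resid, idx, height, settings.sd_limits)
        guesses.append((float(freqs[idx]), float(height), sd))
        resid = resid - height * np.exp(-0.5 * ((freqs - freqs[idx]) / sd) ** 2)
    return guesses


def _refine_peaks(
    freqs: np.ndarray,
    flat: np.ndarray,
    guesses: list[tuple[float, float, float]],
    settings: SpectralSettings,
) -> list[tuple[float, float, float]]:
    """Jointly refine all Gaussians by bounded least squares."""
    if not guesses:
        return []
    lo_f, hi_f = settings.fit_range
    sd_lo, sd_hi = settings.sd_limits
    p0, lower, upper = [], [], []
    for c, a, s in guesses:
        c_lo = max(lo_f, c - 2.0 * s)
        c_hi = min(hi_f, c + 2.0 * s)
        p0 += [np.clip(c, c_lo, c_hi), a, np.clip(s, sd_lo, sd_hi)]
        lower += [c_lo, 0.0, sd_lo]
        upper += [c_hi, np.inf, sd_hi]

    def residual(p: np.ndarray) -> np.ndarray:
        triples = [(p[3 * i], p[3 * i + 1], p[3 * i + 2]) for i in range(len(guesses))]
        return gaussian_sum(freqs, triples) - flat

    try:
        sol = least_squares(residual, p0, bounds=(lower, upper))
        if not sol.success:
            raise RuntimeError(sol.message)
        p = sol.x
        refined = [
            (float(p[3 * i]), float(p[3 * i + 1]), float(p[3 * i + 2]))
            for i in range(len(guesses))
        ]
    except Exception as exc:  # refinement failure -> keep the guesses
        warnings.warn(
            f"joint Gaussian refinement failed ({exc}); keeping unrefined peaks",
            RuntimeWarning,
            stacklevel=2,
        )
        refined = guesses
    # drop peaks that shrank below the absolute height floor
    return [p for p in refined if p[1] >= settings.min_peak_height]


def fit_spectral_model(
    curve: Curve,
    settings: SpectralSettings | None = None,
) -> SpectralFit:
    """Decompose a log10-power spectrum into aperiodic + peaks.

    Steps: (i) robust aperiodic fit (initial least squares, drop the
    upper residual tail, refit); (ii) iterative peak extraction from
    the aperiodic-subtracted spectrum until the tallest point falls
    below ``max(min_peak_height, peak_threshold * residual sd)``;
    (iii) joint bounded least-squares refinement of all Gaussians;
    (iv) aperiodic refit on the peak-subtracted spectrum; (v) goodness
    of fit ``r_squared = 1 - SSE/SST`` of aperiodic + peaks against
    the input, in log10-power space.  Steps (ii)-(iv) run for
    ``refit_rounds`` rounds: the first aperiodic fit is biased upward
    by the peaks it cannot see, so a second pass against the
    peak-corrected background removes that bias (and makes peak
    extraction idempotent: refitting the peak-subtracted spectrum
    finds nothing).
    """
    settings = settings or SpectralSettings()
    freqs_all = curve.grid.points
    lo, hi = settings.fit_range
    if lo < freqs_all[0] - 1e-9 or hi > freqs_all[-1] + 1e-9:
        raise ValueError(
            f"fit range {settings.fit_range} not covered by the grid "
            f"[{freqs_all[0]}, {freqs_all[-1]}]"
        )
    mask = (freqs_all >= lo) & (freqs_all <= hi)
    freqs = freqs_all[mask]
    y = curve.values[mask]

    offset, exponent = _robust_aperiodic_fit(freqs, y, settings.robust_tail)
    peaks: list[tuple[float, float, float]] = []
    for _ in range(max(1, settings.refit_rounds)):
        flat = y - (offset - exponent * np.log10(freqs))
        guesses = _extract_peaks(freqs, flat, settings)
        peaks = _refine_peaks(freqs, flat, guesses, settings)
        peak_vals = gaussian_sum(freqs, peaks)
        offset, exponent = _robust_aperiodic_fit(
            freqs, y - peak_vals, settings.robust_tail
        )
    peak_vals = gaussian_sum(freqs, peaks)

    model_vals = (offset - exponent * np.log10(freqs)) + peak_vals
    sse = float(np.sum((y - model_vals) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - sse / sst if sst > 0 else 1.0

    return SpectralFit(
        offset=offset,
        exponent=exponent,
        peaks=peaks,
        fit_range=settings.fit_range,
        r_squared=r_squared,
        peak_curve=Curve(
            curve.grid,
            gaussian_sum(freqs_all, peaks),
            individual_id=curve.individual_id,
            time_index=curve.time_index,
            segment_id=curve.segment_id,
        ),
        settings=settings,
    )


def peak_curve(fit: SpectralFit, grid: FrequencyGrid) -> Curve:
    """Evaluate the fitted peak-only (periodic) curve on a grid."""
    return Curve(grid, gaussian_sum(grid.points, fit.peaks))
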