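"""Core containers for functional time-series data.

A functional observation is a curve sampled on a shared, strictly
increasing grid (for the EEG application: log-power on a 1.5--30 Hz
frequency grid).  An individual's recording is an ordered sequence of
such curves (a :class:`FunctionalSeries`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

__all__ = [
    "FrequencyGrid",
    "Curve",
    "FunctionalSeries",
    "default_grid",
    "trapezoid_weights",
]


@dataclass(frozen=True)
class FrequencyGrid:
    """Shared sampling grid of the functional domain (Hz for EEG spectra)."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least 2 points in a 1-d array")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.size

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.points.shape == other.points.shape and np.array_equal(
            self.points, other.points
        )

    def __hash__(self) -> int:
        return hash((self.points.size, float(self.points[0]), float(self.points[-1])))

    @property
    def range(self) -> float:
        return float(self.points[-1] - self.points[0])

    @property
    def spacing(self) -> float:
        """Mean spacing; equals the common step on uniform grids."""
        return self.range / (len(self) - 1)

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.points)
        return bool(np.allclose(d, d[0], rtol=rtol, atol=0.0))


def default_grid() -> FrequencyGrid:
    """1.5--30 Hz at 0.5 Hz spacing (58 points), the analysis range used
    for band-limited resting-state EEG spectra."""
    return FrequencyGrid(np.arange(1.5, 30.0 + 0.25, 0.5))


def trapezoid_weights(grid: FrequencyGrid) -> np.ndarray:
    """Quadrature weights of the trapezoidal rule on ``grid``."""
    t = grid.points
    w = np.empty_like(t)
    w[1:-1] = (t[2:] - t[:-2]) / 2.0
    w[0] = (t[1] - t[0]) / 2.0
    w[-1] = (t[-1] - t[-2]) / 2.0
    return w


@dataclass
class Curve:
    """One functional observation on a shared grid.

    ``individual_id`` / ``time_index`` / ``segment_id`` carry provenance
    through the pipeline; they are optional for free-standing curves.
    """

    grid: FrequencyGrid
    values: np.ndarray
    individual_id: Hashable | None = None
    time_index: int | None = None
    segment_id: Hashable | None = None

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.grid),):
            raise ValueError(
                f"curve has {vals.size} values for a {len(self.grid)}-point grid"
            )
        if not np.all(np.isfinite(vals)):
            raise ValueError("curve values must be finite")
        self.values = vals

    def copy(self) -> "Curve":
        return Curve(
            self.grid,
            self.values.copy(),
            individual_id=self.individual_id,
            time_index=self.time_index,
            segment_id=self.segment_id,
        )


@dataclass
class FunctionalSeries:
    """Time-ordered sequence of curves for one individual."""

    individual_id: Hashable
    curves: list[Curve] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("a functional series needs at least one curve")
        grid = self.curves[0].grid
        for c in self.curves:
            if c.grid != grid:
                raise ValueError("all curves in a series must share one grid")
        idx = [c.time_index for c in self.curves]
        if any(i is None for i in idx):
            for k, c in enumerate(self.curves):
                c.time_index = k
        elif any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("time indices must be strictly increasing")

    @property
    def grid(self) -> FrequencyGrid:
        return self.curves[0].grid

    def __len__(self) -> int:
        return len(self.curves)

    @property
    def values(self) -> np.ndarray:
        """(K, G) matrix of the stacked curve values."""
        return np.vstack([c.values for c in self.curves])


def stack_values(curves: Sequence[Curve]) -> np.ndarray:
    """Stack a curve list into an (n, G) matrix (shared-grid checked)."""
    if not curves:
        raise ValueError("empty curve list")
    grid = curves[0].grid
    for c in curves:
        if c.grid != grid:
            raise ValueError("curves do not share a grid")
    return np.vstack([c.values for c in curves])
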