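"""File formats, paradigm arithmetic, and the feature-table export.

Curve matrices are plain CSV: one row per functional observation,
columns are the grid values, and the header row carries the grid
points.  A companion metadata CSV aligns row-for-row on
``(individual_id, time_index)`` and optionally carries segment ids and
true states.  Gzip-compressed variants are read and written
transparently (pandas dispatches on the ``.gz`` suffix).

The paradigm helpers implement the recording-block arithmetic of an
alternating eyes-closed / eyes-open resting-state protocol: one
spectrum per second, eyes-closed blocks trimmed by a leading and
trailing buffer, giving the retained observation indices per segment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Curve, FrequencyGrid, FunctionalSeries
from .fpca import FPCAModel, individual_mean_scores
from .occupancy import MIXED_LABEL, OccupancySummary

logger = logging.getLogger(__name__)

__all__ = [
    "ParadigmSpec",
    "default_paradigm",
    "segment_eyes_closed",
    "taper_count",
    "read_dataset",
    "write_dataset",
    "dataset_to_frames",
    "export_feature_table",
]

EYES_CLOSED = "eyes_closed"
EYES_OPEN = "eyes_open"


# ---------------------------------------------------------------------------
# paradigm helpers


@dataclass(frozen=True)
class ParadigmSpec:
    """Block structure of an alternating resting-state recording.

    ``blocks`` lists (condition, duration-in-seconds) pairs; sampling
    is one observation per second; ``buffer`` seconds are trimmed from
    each end of every eyes-closed block.
    """

    blocks: tuple[tuple[str, int], ...]
    buffer: int = 2

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("paradigm needs at least one block")
        for cond, dur in self.blocks:
            if cond not in (EYES_CLOSED, EYES_OPEN):
                raise ValueError(f"unknown condition {cond!r}")
            if dur <= 0:
                raise ValueError("block durations must be positive")
        if self.buffer < 0:
            raise ValueError("buffer must be nonnegative")
        ec = [d for c, d in self.blocks if c == EYES_CLOSED]
        if ec and self.buffer >= min(ec) / 2:
            raise ValueError(
                f"buffer {self.buffer}s must be under half the shortest "
                f"eyes-closed block ({min(ec)}s)"
            )

    @property
    def total_duration(self) -> int:
        return sum(d for _, d in self.blocks)


def default_paradigm() -> ParadigmSpec:
    """Five cycles of 40 s eyes closed / 20 s eyes open (300 s total)."""
    return ParadigmSpec(blocks=((EYES_CLOSED, 40), (EYES_OPEN, 20)) * 5, buffer=2)


@dataclass(frozen=True)
class SegmentationResult:
    """Retained one-per-second observation indices per eyes-closed segment."""

    segments: tuple[tuple[int, ...], ...]  # retained 0-based second indices
    per_segment_counts: tuple[int, ...]
    total_retained: int
    total_eyes_closed: int  # untrimmed eyes-closed seconds

    @property
    def retained_indices(self) -> tuple[int, ...]:
        return tuple(i for seg in self.segments for i in seg)


def segment_eyes_closed(spec: ParadigmSpec) -> SegmentationResult:
    """Trim each eyes-closed block by the buffer and return what survives.

    Indices are 0-based seconds into the full recording.  With the
    default paradigm (5 x [40 s closed, 20 s open], 2 s buffer) this
    yields 5 segments of 36 retained observations (180 total) out of
    200 untrimmed eyes-closed seconds.
    """
    segments: list[tuple[int, ...]] = []
    t = 0
    total_ec = 0
    for cond, dur in spec.blocks:
        if cond == EYES_CLOSED:
            total_ec += dur
            kept = tuple(range(t + spec.buffer, t + dur - spec.buffer))
            segments.append(kept)
        t += dur
    counts = tuple(len(s) for s in segments)
    return SegmentationResult(
        segments=tuple(segments),
        per_segment_counts=counts,
        total_retained=sum(counts),
        total_eyes_closed=total_ec,
    )


def taper_count(time_half_bandwidth_product: float) -> int:
    """Number of Slepian tapers under the 2TW - 1 rule."""
    tw = time_half_bandwidth_product
    if tw < 1:
        raise ValueError("time half-bandwidth product must be at least 1")
    return int(np.floor(2.0 * tw)) - 1


# ---------------------------------------------------------------------------
# dataset CSV round trip


def dataset_to_frames(
    dataset: Sequence[FunctionalSeries],
    true_paths: Mapping[Hashable, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Curve matrix and metadata table for a dataset."""
    grid = dataset[0].grid
    rows, meta = [], []
    for series in dataset:
        truth = true_paths.get(series.individual_id) if true_paths else None
        for k, c in enumerate(series.curves):
            rows.append(c.values)
            entry = {
                "individual_id": series.individual_id,
                "time_index": c.time_index,
                "segment_id": c.segment_id if c.segment_id is not None else "",
            }
            if truth is not None:
                entry["true_state"] = int(truth[k])
            meta.append(entry)
    curves = pd.DataFrame(np.vstack(rows), columns=[repr(float(p)) for p in grid.points])
    return curves, pd.DataFrame(meta)


def write_dataset(
    dataset: Sequence[FunctionalSeries],
    curves_path,
    meta_path,
    true_paths: Mapping[Hashable, np.ndarray] | None = None,
) -> None:
    """Write curve and metadata CSVs (grid points in the curve header).

    Values are written with ``repr`` round-trip precision so a
    write-read cycle reproduces finite doubles bit-for-bit.
    """
    curves, meta = dataset_to_frames(dataset, true_paths)
    curves.to_csv(curves_path, index=False, float_format=lambda v: repr(float(v)))
    meta.to_csv(meta_path, index=False)


def read_dataset(curves_path, meta_path) -> list[FunctionalSeries]:
    """Read a curve matrix + metadata pair into functional series.

    The curve header must be a strictly increasing grid; curve and
    metadata rows align 1:1; duplicated (individual, time) keys are an
    error; unsorted time indices are accepted and sorted with a
    warning.
    """
    curves = pd.read_csv(curves_path, float_precision="round_trip")
    meta = pd.read_csv(meta_path)
    try:
        points = np.array([float(c) for c in curves.columns])
    except ValueError as exc:
        raise ValueError("curve header must hold numeric grid points") from exc
    if np.any(np.diff(points) <= 0):
        raise ValueError("grid header must be strictly increasing")
    grid = FrequencyGrid(points)
    if len(curves) != len(meta):
        raise ValueError(
            f"curve rows ({len(curves)}) and metadata rows ({len(meta)}) differ"
        )
    for col in ("individual_id", "time_index"):
        if col not in meta.columns:
            raise ValueError(f"metadata is missing the {col!r} column")
    dup = meta.duplicated(subset=["individual_id", "time_index"])
    if dup.any():
        first = meta.loc[dup.idxmax()]
        raise ValueError(
            "duplicated (individual_id, time_index) key: "
            f"({first['individual_id']!r}, {first['time_index']!r})"
        )
    values = curves.to_numpy(float)
    has_segment = "segment_id" in meta.columns and meta["segment_id"].notna().any()

    series: list[FunctionalSeries] = []
    for pid, group in meta.groupby("individual_id", sort=False):
        idx = group.index.to_numpy()
        times = group["time_index"].to_numpy()
        if np.any(np.diff(times) <= 0):
            warnings.warn(
                f"time indices for individual {pid!r} are not sorted; sorting",
                RuntimeWarning,
                stacklevel=2,
            )
            order = np.argsort(times, kind="stable")
            idx, times = idx[order], times[order]
        curves_list = [
            Curve(
                grid,
                values[i],
                individual_id=pid,
                time_index=int(t),
                segment_id=(meta.at[i, "segment_id"] if has_segment else None),
            )
            for i, t in zip(idx, times)
        ]
        series.append(FunctionalSeries(pid, curves_list))
    return series


# ---------------------------------------------------------------------------
# feature table for downstream regression


def export_feature_table(
    summaries: Sequence[OccupancySummary],
    fpca_models: Mapping[int, FPCAModel],
    covariates: pd.DataFrame | None = None,
    threshold: float = 0.8,
    n_score_components: int = 5,
) -> pd.DataFrame:
    """One row per individual: state dynamics plus dominant-state FPCA
    scores, ready for any regression tool.

    Every individual receives scores from its dominant state's model
    (mean of its observation-level scores there); individuals below
    the dominant-time threshold are flagged ``mixed`` in the
    ``group`` column but scored all the same.  Rows are sorted by
    individual id so output is deterministic under input reordering.
    """
    score_cache = {
        state: individual_mean_scores(model, n_components=n_score_components)
        for state, model in fpca_models.items()
    }
    ncomp = max((s.shape[1] for s in score_cache.values()), default=0)
    rows = []
    for s in summaries:
        grouped = s.dominant_pct >= threshold
        row: dict = {
            "individual_id": s.individual_id,
            "dominant_state": s.dominant_state,
            "group": s.dominant_state if grouped else MIXED_LABEL,
            "n_states_visited": s.n_states_visited,
            "n_transitions": s.n_transitions,
            "dominant_pct": s.dominant_pct,
        }
        scores = score_cache.get(s.dominant_state)
        if scores is None:
            # no FPCA model for this state (e.g. too few curves): NaN scores
            for c in range(ncomp):
                row[f"fpc_score_{c + 1}"] = np.nan
            rows.append(row)
            continue
        if s.individual_id not in scores.index:
            raise ValueError(
                f"individual {s.individual_id!r} has no scores in its "
                f"dominant state {s.dominant_state}"
            )
        for c in range(ncomp):
            col = f"fpc_score_{c + 1}"
            row[col] = scores.at[s.individual_id, col] if col in scores else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("individual_id", kind="stable")
    table = table.reset_index(drop=True)
    if covariates is not None:
        table = table.merge(covariates, on="individual_id", how="left")
    return table
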