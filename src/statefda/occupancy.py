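"""Per-individual latent-state dynamics from decoded state paths.

For each individual we summarise the Viterbi path into: the set and
number of states visited, the number of transitions (adjacent unequal
state pairs), the fraction of time in each state, and the dominant
state.  Individuals spending at least a threshold fraction (default
80%) of their time in one state form that state's dominant-state
group; the rest are "mixed".  Counts of the visited-state combinations
partition the cohort (the data behind a Venn diagram of states).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd

from .fhmm import ViterbiPath

__all__ = [
    "OccupancySummary",
    "summarise_path",
    "dominant_state_groups",
    "visited_combinations",
    "summaries_to_frame",
]

MIXED_LABEL = "mixed"


@dataclass
class OccupancySummary:
    """Latent-state dynamics statistics for one individual."""

    individual_id: Hashable
    n_states_visited: int
    n_transitions: int
    state_proportions: np.ndarray  # length N, sums to 1
    dominant_state: int
    dominant_pct: float
    visited_set: frozenset[int]
    dominant_tie: bool = False


def summarise_path(
    path: ViterbiPath,
    n_states: int,
    segment_starts: Iterable[int] = (),
) -> OccupancySummary:
    """Summarise a decoded state path.

    ``segment_starts`` lists 0-based positions at which a new recording
    segment begins; the pairs straddling those positions are excluded
    from the transition count (used when the chain is restarted at
    segment boundaries).  Proportions always use all decoded steps.
    """
    states = np.asarray(path.states, dtype=int)
    if states.size == 0:
        raise ValueError("empty path")
    if states.min() < 1 or states.max() > n_states:
        raise ValueError(
            f"path labels must lie in 1..{n_states}, got range "
            f"[{states.min()}, {states.max()}]"
        )
    changes = states[1:] != states[:-1]
    for s in segment_starts:
        if 1 <= s < states.size:
            changes[s - 1] = False
    n_transitions = int(changes.sum())
    counts = np.bincount(states - 1, minlength=n_states)
    proportions = counts / states.size
    dominant = int(np.argmax(proportions))  # lowest label on ties
    tie = int((proportions == proportions[dominant]).sum()) > 1
    return OccupancySummary(
        individual_id=path.individual_id,
        n_states_visited=int((counts > 0).sum()),
        n_transitions=n_transitions,
        state_proportions=proportions,
        dominant_state=dominant + 1,
        dominant_pct=float(proportions[dominant]),
        visited_set=frozenset(int(s) for s in np.unique(states)),
        dominant_tie=tie,
    )


def dominant_state_groups(
    summaries: Sequence[OccupancySummary],
    threshold: float = 0.8,
) -> dict[Hashable, int | str]:
    """Assign each individual to its dominant state's group, or "mixed".

    An individual is grouped iff it spent at least ``threshold`` of its
    decoded time in one state ("80% or more" is inclusive).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    out: dict[Hashable, int | str] = {}
    for s in summaries:
        out[s.individual_id] = (
            s.dominant_state if s.dominant_pct >= threshold else MIXED_LABEL
        )
    return out


def group_sizes(groups: dict[Hashable, int | str]) -> Counter:
    return Counter(groups.values())


def visited_combinations(
    summaries: Sequence[OccupancySummary],
    n_states: int | None = None,
) -> dict[frozenset[int], int]:
    """Count individuals per combination of visited states.

    The counts partition the individuals.  For small state spaces
    (N <= 4) every nonempty subset is reported, including zero counts,
    so the table maps directly onto a Venn diagram.
    """
    counts: Counter[frozenset[int]] = Counter(s.visited_set for s in summaries)
    if n_states is None:
        n_states = max((max(s.visited_set) for s in summaries), default=0)
    out: dict[frozenset[int], int] = {}
    if n_states <= 4:
        labels = range(1, n_states + 1)
        for r in range(1, n_states + 1):
            for subset in combinations(labels, r):
                out[frozenset(subset)] = 0
    for key, n in counts.items():
        out[key] = n
    return out


def combinations_to_frame(
    combos: dict[frozenset[int], int]
) -> pd.DataFrame:
    """Tabulate combination counts (subset as sorted label string)."""
    total = sum(combos.values())
    rows = [
        {
            "states": "+".join(str(s) for s in sorted(k)),
            "count": v,
            "percent": 100.0 * v / total if total else 0.0,
        }
        for k, v in sorted(combos.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))
    ]
    return pd.DataFrame(rows, columns=["states", "count", "percent"])


def summaries_to_frame(summaries: Sequence[OccupancySummary]) -> pd.DataFrame:
    """Per-individual summary table (proportions as fractions)."""
    n_states = summaries[0].state_proportions.size if summaries else 0
    rows = []
    for s in summaries:
        row = {
            "individual_id": s.individual_id,
            "n_states_visited": s.n_states_visited,
            "n_transitions": s.n_transitions,
            "dominant_state": s.dominant_state,
            "dominant_pct": s.dominant_pct,
            "dominant_tie": s.dominant_tie,
        }
        for i in range(n_states):
            row[f"prop_state_{i + 1}"] = s.state_proportions[i]
        rows.append(row)
    return pd.DataFrame(rows)
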