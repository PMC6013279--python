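"""Active-cell calling from pooled ΔF distributions.

All ΔF (T3 − T1) values of one animal, across every cell and imaged
session, are pooled into a single distribution; its empirical shape is
near-symmetric double-exponential with mode ≈ 0 and a long positive tail.
A cell is called active on a session when its ΔF is positive and exceeds
the pooled mean by 1.5 pooled (sample) standard deviations — a one-sided
cut intended to admit roughly 5% of values.  Cells active on at least one
session form the animal's "active cell pool", the universe for the
overlap null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivityMatrix",
    "ActiveCellPool",
    "pooled_threshold",
    "call_active",
    "percent_active",
    "active_cell_pool",
    "collapse_conditions",
]


@dataclass(frozen=True)
class ActivityMatrix:
    """Boolean cells × sessions active calls for one animal."""

    animal_id: str
    active: pd.DataFrame  # bool, index = cell ids, columns = session labels
    threshold: float
    total_cells: int


@dataclass(frozen=True)
class ActiveCellPool:
    """Cells active on at least one session; its size is the pool size t."""

    animal_id: str
    cells: tuple

    @property
    def t(self) -> int:
        return len(self.cells)


def pooled_threshold(deltas) -> float:
    """Active-cell threshold: pooled mean + 1.5 × pooled sample SD.

    ``deltas`` holds every ΔF value of one animal across cells and
    sessions (NaNs, e.g. from incompletely tracked cells, are ignored).
    An all-identical pool degenerates to SD = 0; the threshold then equals
    the mean and a warning is raised.
    """
    arr = np.asarray(deltas, dtype=float).ravel()
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 finite ΔF values to pool")
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        warnings.warn(
            "pooled ΔF values are all identical; threshold degenerates to the mean",
            stacklevel=2,
        )
    return float(arr.mean()) + 1.5 * sd


def call_active(
    deltas: pd.DataFrame,
    threshold: float,
    animal_id: str = "",
) -> ActivityMatrix:
    """Call active cells: ΔF strictly above threshold *and* positive.

    ``deltas`` is a cells × sessions table of ΔF values computed from the
    same animal whose pooled distribution produced ``threshold``.  The
    positivity clause is applied explicitly even though a positive
    threshold implies it.
    """
    if not isinstance(deltas, pd.DataFrame):
        deltas = pd.DataFrame(np.asarray(deltas, dtype=float))
    if deltas.shape[0] == 0 or deltas.shape[1] == 0:
        raise ValueError("ΔF table must contain at least one cell and one session")
    active = (deltas > threshold) & (deltas > 0)
    return ActivityMatrix(
        animal_id=animal_id,
        active=active,
        threshold=float(threshold),
        total_cells=int(deltas.shape[0]),
    )


def percent_active(matrix: ActivityMatrix, session) -> float:
    """Percentage of the animal's detected cells active on one session."""
    if matrix.total_cells <= 0:
        raise ValueError("total_cells must be positive")
    return 100.0 * int(matrix.active[session].sum()) / matrix.total_cells


def active_cell_pool(matrix: ActivityMatrix) -> ActiveCellPool:
    """Union of the per-session active sets (cells active >= 1 session)."""
    ever = matrix.active.any(axis=1)
    return ActiveCellPool(
        animal_id=matrix.animal_id,
        cells=tuple(matrix.active.index[ever]),
    )


def collapse_conditions(
    values: Mapping,
    grouping: Mapping[str, Sequence],
) -> dict[str, float]:
    """Collapse per-session values into condition-block means.

    ``grouping`` maps block names (e.g. training / control / retention /
    novelty) to the session labels they contain; each block's value is the
    arithmetic mean of its sessions.  Empty blocks are rejected.
    """
    out: dict[str, float] = {}
    for block, sessions in grouping.items():
        sessions = list(sessions)
        if not sessions:
            raise ValueError(f"condition block {block!r} contains no sessions")
        missing = [s for s in sessions if s not in values]
        if missing:
            raise ValueError(f"block {block!r} references unknown sessions {missing}")
        out[block] = float(np.mean([values[s] for s in sessions]))
    return out
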