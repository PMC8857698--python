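"""Natural-break segmentation of shifts.

Events inside one (encounter, shift) arrive in bursts separated by quiet
gaps.  The break interval that separates "same burst" from "new burst" is
chosen on a 30-120 minute grid (5-minute steps) by a two-class
natural-breaks optimization: each candidate boundary splits the pooled gap
sample into gaps below/above the candidate, and the goodness of variance
fit GVF = 1 - SSD_within / SSD_total is maximized.  A gap >= the chosen
interval starts a new segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractError

#: candidate break intervals in minutes: 30, 35, ..., 120
DEFAULT_GRID = tuple(range(30, 125, 5))


@dataclass
class GapSample:
    """Consecutive-event gaps pooled across (encounter, shift) groups."""

    gaps: np.ndarray
    keys: pd.DataFrame  # encounter_id, shift_number per gap

    def __len__(self) -> int:
        return len(self.gaps)


@dataclass
class BreakSelection:
    candidate_grid: tuple[int, ...]
    gvf_by_candidate: np.ndarray
    chosen_interval: int
    degenerate: bool = False


@dataclass
class Segment:
    """A maximal run of events uninterrupted by a gap >= the break interval."""

    encounter_id: str
    shift_number: int
    segment_id: int
    event_index: np.ndarray
    roles: frozenset[str]
    t_start: float
    t_end: float


def collect_gaps(master_log: pd.DataFrame) -> GapSample:
    """One gap per adjacent same-(encounter, shift) event pair.

    Requires the log sorted by (encounter, shift, t_norm); same-time fan-out
    events contribute zero gaps.
    """
    gaps = []
    keys = []
    for (enc, shift), grp in master_log.groupby(
        ["encounter_id", "shift_number"], sort=False
    ):
        t = grp["t_norm"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ContractError(
                f"master log not sorted by t_norm within ({enc}, shift {shift})"
            )
        if len(t) > 1:
            g = np.diff(t)
            gaps.append(g)
            keys.append(
                pd.DataFrame(
                    {"encounter_id": enc, "shift_number": shift, "gap": g}
                )
            )
    if gaps:
        all_gaps = np.concatenate(gaps)
        key_df = pd.concat(keys, ignore_index=True)
    else:
        all_gaps = np.array([], dtype=float)
        key_df = pd.DataFrame(columns=["encounter_id", "shift_number", "gap"])
    return GapSample(gaps=all_gaps, keys=key_df)


def gvf_two_class(gaps: np.ndarray, boundary: float) -> float:
    """Goodness of variance fit of the 2-class split {g < boundary}, {g >= boundary}.

    An empty class contributes zero to the within-class sum of squared
    deviations.  Undefined (returns 1.0 is *not* assumed) when the total SSD
    is zero; callers must handle that degenerate case.
    """
    gaps = np.asarray(gaps, dtype=float)
    total = float(np.sum((gaps - gaps.mean()) ** 2))
    low = gaps[gaps < boundary]
    high = gaps[gaps >= boundary]
    within = 0.0
    for cls in (low, high):
        if len(cls):
            within += float(np.sum((cls - cls.mean()) ** 2))
    return 1.0 - within / total


def select_break_interval(
    sample: GapSample | np.ndarray, grid=DEFAULT_GRID
) -> BreakSelection:
    """Choose the grid boundary maximizing GVF; ties go to the smallest
    interval (finest segmentation consistent with a 30-minute minimum break).

    If all gaps are identical the optimization is degenerate and the grid
    minimum is returned with a warning.
    """
    gaps = sample.gaps if isinstance(sample, GapSample) else np.asarray(sample, dtype=float)
    if not len(gaps):
        raise ContractError("cannot select a break interval from an empty gap sample")
    grid = tuple(int(c) for c in grid)
    total = float(np.sum((gaps - gaps.mean()) ** 2))
    if total == 0.0:
        warnings.warn(
            "all gaps identical: natural-break optimization is degenerate; "
            f"falling back to the grid minimum ({grid[0]} min)",
            stacklevel=2,
        )
        return BreakSelection(
            candidate_grid=grid,
            gvf_by_candidate=np.zeros(len(grid)),
            chosen_interval=grid[0],
            degenerate=True,
        )
    gvf = np.array([gvf_two_class(gaps, c) for c in grid])
    chosen = grid[int(np.argmax(gvf))]  # argmax takes the first (smallest) maximizer
    return BreakSelection(
        candidate_grid=grid, gvf_by_candidate=gvf, chosen_interval=chosen
    )


def segment_shifts(
    master_log: pd.DataFrame, chosen_interval: float
) -> tuple[pd.DataFrame, list[Segment]]:
    """Assign ``segment_id`` to every event and return the segment list.

    A new segment starts exactly when the gap to the previous event is
    >= ``chosen_interval``; IDs are dense from 0 within each
    (encounter, shift).
    """
    out = master_log.copy()
    seg_ids = np.full(len(out), -1, dtype=np.int64)
    segments: list[Segment] = []
    pos = out.index.to_numpy()
    for (enc, shift), grp in out.groupby(["encounter_id", "shift_number"], sort=False):
        t = grp["t_norm"].to_numpy(dtype=float)
        if np.any(np.diff(t) < 0):
            raise ContractError(
                f"master log not sorted by t_norm within ({enc}, shift {shift})"
            )
        breaks = np.zeros(len(t), dtype=np.int64)
        if len(t) > 1:
            breaks[1:] = (np.diff(t) >= chosen_interval).astype(np.int64)
        ids = np.cumsum(breaks)
        rows = grp.index.to_numpy()
        seg_ids[np.searchsorted(pos, rows)] = ids
        for sid in range(ids[-1] + 1):
            mask = ids == sid
            segments.append(
                Segment(
                    encounter_id=enc,
                    shift_number=int(shift),
                    segment_id=sid,
                    event_index=rows[mask],
                    roles=frozenset(grp["functional_role"].to_numpy()[mask]),
                    t_start=float(t[mask][0]),
                    t_end=float(t[mask][-1]),
                )
            )
    out["segment_id"] = seg_ids
    return out, segments
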