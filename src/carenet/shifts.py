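"""Shift-rotation arithmetic.

Clinical work is divided into 12-hour rotations: day = [07:00, 19:00) and
night = [19:00, 07:00), half-open at minute resolution.  Every wall-clock
instant belongs to exactly one *global* shift index; an encounter's shift
number is the global index of the event minus the global index of ED
arrival, so the arrival shift is number 0 and the number increments at each
07:00/19:00 boundary crossed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: minutes after midnight at which the day shift starts
DAY_START_MINUTE = 7 * 60
#: length of one shift rotation in minutes
SHIFT_MINUTES = 12 * 60

_EPOCH = pd.Timestamp("2000-01-01")

DAY = "day"
NIGHT = "night"


def _abs_minutes(ts) -> np.ndarray:
    """Minutes since a fixed epoch, as float64 (vectorised)."""
    delta = pd.to_datetime(ts) - _EPOCH
    if isinstance(delta, pd.Timedelta):
        return np.asarray(delta.total_seconds() / 60.0)
    return delta.dt.total_seconds().to_numpy() / 60.0


def global_shift_index(ts) -> np.ndarray:
    """Global shift index of a timestamp (or series of timestamps).

    Even indices are day shifts, odd indices are night shifts.
    """
    minutes = _abs_minutes(ts)
    return np.floor((minutes - DAY_START_MINUTE) / SHIFT_MINUTES).astype(np.int64)


def shift_type_of_index(index) -> np.ndarray:
    """``"day"`` for even global indices, ``"night"`` for odd."""
    idx = np.asarray(index)
    return np.where(idx % 2 == 0, DAY, NIGHT)


def shift_labels(arrival_clock, t_norm_minutes):
    """Shift number and shift type for events at ``arrival + t_norm`` minutes.

    Parameters
    ----------
    arrival_clock
        Scalar or series of encounter arrival wall-clock timestamps.
    t_norm_minutes
        Scalar or array of normalized event times (minutes from ED arrival).

    Returns
    -------
    (shift_number, shift_type)
        ``shift_number`` is 0 for the arrival shift; ``shift_type`` follows
        the wall clock implied by ``arrival + t_norm``.
    """
    arr = pd.to_datetime(arrival_clock)
    t = np.asarray(t_norm_minutes, dtype=float)
    g_arrival = global_shift_index(arr)
    event_minutes = _abs_minutes(arr) + t
    g_event = np.floor(
        (event_minutes - DAY_START_MINUTE) / SHIFT_MINUTES
    ).astype(np.int64)
    return g_event - g_arrival, shift_type_of_index(g_event)


def shift_type_of_clock(ts):
    """Day/night label of a wall-clock timestamp."""
    return shift_type_of_index(global_shift_index(ts))
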