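"""Master event-log preparation.

Raw EHR activity records become clean, role-resolved events in five steps:

1. normalize timestamps to minutes from ED arrival,
2. exclude system-initiated, student and incomplete records,
3. infer the care location of notes and flow sheets from the ADT timeline,
4. resolve each health-care professional to a functional role
   (service-prefixed generic role),
5. fan out multi-HCP records into same-time events and label each event
   with its shift number and shift type.

Every filtering step returns both partitions, with a machine-readable
reason code on each excluded row, so that |kept| + |excluded| = |input|.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import shifts
from .errors import ContractError, DataError
from .roles import (
    ENCOUNTER_RESOLVED_ROLES,
    FIXED_SERVICE_ROLES,
    LOCATION_SERVICE,
    ROLE_ABBREVIATIONS,
    make_label,
)

logger = logging.getLogger(__name__)

_MISSING = ""

#: exclusion reason codes
REASON_SYSTEM = "system_initiated"
REASON_STUDENT = "student"
REASON_INCOMPLETE = "incomplete"
REASON_PRE_ARRIVAL = "pre_arrival"
REASON_UNRESOLVED = "unresolved_role"
REASON_OFF_BASE = "off_base_unit"

EVENT_COLUMNS = [
    "encounter_id",
    "t_norm",
    "activity_type",
    "hcp_id",
    "functional_role",
    "care_location",
    "shift_number",
    "shift_type",
    "segment_id",
]


def normalize_timestamps(
    records: pd.DataFrame, encounters: pd.DataFrame, return_excluded: bool = False
):
    """Replace wall-clock timestamps with minutes from ED arrival (``t_norm``).

    Records timestamped before arrival (pre-registration artifacts) are
    excluded with a logged count rather than clamped to zero.  Raises
    :class:`DataError` for records referencing unknown encounters.
    """
    arrivals = encounters.set_index("encounter_id")["arrival_clock"]
    unknown = ~records["encounter_id"].isin(arrivals.index)
    if unknown.any():
        bad = sorted(records.loc[unknown, "encounter_id"].unique())
        raise DataError(f"records reference unknown encounter IDs: {bad[:5]}")
    out = records.copy()
    arr = arrivals.loc[out["encounter_id"]].to_numpy()
    out["t_norm"] = (
        (pd.to_datetime(out["timestamp"]).to_numpy() - arr) / np.timedelta64(1, "m")
    ).astype(float)
    pre = out["t_norm"] < 0
    if pre.any():
        logger.info("excluded %d records timestamped before ED arrival", int(pre.sum()))
    kept = out[~pre].reset_index(drop=True)
    if return_excluded:
        excluded = out[pre].reset_index(drop=True)
        excluded = excluded.assign(exclusion_reason=REASON_PRE_ARRIVAL)
        return kept, excluded
    return kept


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop system-initiated, student-initiated and incomplete records.

    Returns ``(kept, excluded)``; the two frames partition the input and each
    excluded row carries an ``exclusion_reason`` code.
    """
    reason = pd.Series(_MISSING, index=records.index, dtype=object)
    incomplete = (
        records["hcp_id"].fillna(_MISSING).eq(_MISSING)
        | records["generic_role"].fillna(_MISSING).eq(_MISSING)
        | ~records["activity_type"].isin(
            ("note", "procedure_order", "medication_order", "flowsheet", "medication_admin")
        )
        | records["encounter_id"].fillna(_MISSING).eq(_MISSING)
    )
    reason[incomplete] = REASON_INCOMPLETE
    reason[records["student"].astype(bool)] = REASON_STUDENT
    reason[records["system_initiated"].astype(bool)] = REASON_SYSTEM
    drop = reason != _MISSING
    kept = records[~drop].reset_index(drop=True)
    excluded = records[drop].assign(exclusion_reason=reason[drop]).reset_index(drop=True)
    return kept, excluded


def infer_location(t_norm: float, timeline) -> str:
    """Care location at ``t_norm`` under the half-open ``[start, end)`` ADT
    convention; times past the final interval take the last location."""
    if t_norm < 0:
        raise ContractError(f"t_norm must be non-negative, got {t_norm}")
    if not len(timeline):
        raise ContractError("empty location timeline")
    for loc, start, end in timeline:
        if start <= t_norm < end:
            return loc
    return timeline[-1][0]


def build_timelines(adt: pd.DataFrame) -> dict[str, list[tuple[str, float, float]]]:
    """Per-encounter ordered ``(location, start_minute, end_minute)`` lists."""
    timelines: dict[str, list[tuple[str, float, float]]] = {}
    for enc_id, grp in adt.groupby("encounter_id", sort=False):
        grp = grp.sort_values("start_minute")
        tl = list(zip(grp["location"], grp["start_minute"].astype(float), grp["end_minute"].astype(float)))
        if tl[0][1] != 0:
            raise DataError(f"ADT timeline for {enc_id} does not start at minute 0")
        for (_, _, e_prev), (_, s_next, _) in zip(tl, tl[1:]):
            if e_prev != s_next:
                raise DataError(f"ADT timeline for {enc_id} is not contiguous")
        timelines[enc_id] = tl
    return timelines


def infer_locations(records: pd.DataFrame, adt: pd.DataFrame) -> pd.DataFrame:
    """Fill ``care_location`` for notes and flow sheets from the ADT timeline.

    Order/administration records keep their recorded location.
    """
    timelines = build_timelines(adt)
    out = records.copy()
    needs = out["activity_type"].isin(("note", "flowsheet"))
    locs = out["care_location"].to_numpy(dtype=object, copy=True)
    for i in np.flatnonzero(needs.to_numpy()):
        enc = out["encounter_id"].iat[i]
        tl = timelines.get(enc)
        if tl is None:
            raise DataError(f"no ADT timeline for encounter {enc}")
        locs[i] = infer_location(float(out["t_norm"].iat[i]), tl)
    out["care_location"] = locs
    return out


# --------------------------------------------------------------------------
# functional-role resolution


def _mode_with_tiebreak(values: pd.Series, order_key: pd.Series) -> str:
    """Most frequent value; ties broken by the value whose earliest
    ``order_key`` is smallest, then lexicographically."""
    counts = values.value_counts()
    top = counts[counts == counts.max()].index
    if len(top) == 1:
        return top[0]
    firsts = {v: order_key[values == v].min() for v in top}
    return min(top, key=lambda v: (firsts[v], v))


def resolve_functional_roles(
    records: pd.DataFrame, roster: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign a functional role to every record.

    * Fixed-service roles (attendings, fellows, PAs, and NPs with service
      evidence) take the modal service of their notes across the dataset,
      falling back to the roster.
    * Residents and radiology technicians are resolved per encounter from
      the modal cosigner service of their notes in that encounter (mode ties
      broken by the most recent note).
    * Nurses, unit NPs and the remaining allied HCPs take the service bound
      to the modal location of all their activities (ties: earliest-seen
      location, then lexicographic); their note/flow-sheet records at other
      locations are excluded as ``off_base_unit``.

    HCPs with no resolvable service have all their records excluded with
    reason ``unresolved_role``.  Returns ``(resolved, excluded)``.
    """
    out = records.copy().reset_index(drop=True)
    roster_service: dict[str, str] = {}
    if roster is not None and len(roster):
        roster_service = {
            r["hcp_id"]: r.get("true_service", _MISSING) or _MISSING
            for _, r in roster.iterrows()
            if (r.get("true_service", _MISSING) or _MISSING) != _MISSING
        }

    svc = out["service"].fillna(_MISSING)
    cosvc = out["cosigner_service"].fillna(_MISSING)
    is_note = out["activity_type"] == "note"

    functional = pd.Series(_MISSING, index=out.index, dtype=object)
    reason = pd.Series(_MISSING, index=out.index, dtype=object)

    for hcp_id, idx in out.groupby("hcp_id", sort=True).groups.items():
        idx = pd.Index(idx)
        grp_role = out.loc[idx[0], "generic_role"]
        if grp_role not in ROLE_ABBREVIATIONS:
            reason[idx] = REASON_UNRESOLVED
            continue

        note_services = svc[idx][is_note[idx] & (svc[idx] != _MISSING)]
        has_service_evidence = len(note_services) > 0 or hcp_id in roster_service
        fixed = grp_role in FIXED_SERVICE_ROLES or (
            grp_role == "nurse_practitioner" and has_service_evidence
        )

        if fixed:
            if len(note_services):
                service = _mode_with_tiebreak(note_services, out.loc[note_services.index, "t_norm"])
            elif hcp_id in roster_service:
                service = roster_service[hcp_id]
            else:
                reason[idx] = REASON_UNRESOLVED
                continue
            functional[idx] = make_label(service, grp_role)
        elif grp_role in ENCOUNTER_RESOLVED_ROLES:
            for enc_id, eidx in out.loc[idx].groupby("encounter_id", sort=False).groups.items():
                eidx = pd.Index(eidx)
                cos = cosvc[eidx][is_note[eidx] & (cosvc[eidx] != _MISSING)]
                if not len(cos):
                    reason[eidx] = REASON_UNRESOLVED
                    continue
                counts = cos.value_counts()
                top = counts[counts == counts.max()].index
                if len(top) == 1:
                    service = top[0]
                else:
                    # tie -> service of the most recent note among the tied
                    lasts = {v: out.loc[cos[cos == v].index, "t_norm"].max() for v in top}
                    service = max(sorted(top), key=lambda v: lasts[v])
                functional[eidx] = make_label(service, grp_role)
        else:
            loc = out.loc[idx, "care_location"].fillna(_MISSING)
            located = loc[loc != _MISSING]
            if not len(located):
                reason[idx] = REASON_UNRESOLVED
                continue
            base = _mode_with_tiebreak(located, out.loc[located.index, "t_norm"])
            service = LOCATION_SERVICE.get(base)
            if service is None:
                reason[idx] = REASON_UNRESOLVED
                continue
            functional[idx] = make_label(service, grp_role)
            off = idx[
                out.loc[idx, "activity_type"].isin(("note", "flowsheet"))
                & (out.loc[idx, "care_location"] != base)
            ]
            reason[off] = REASON_OFF_BASE
            functional[off] = _MISSING

    drop = reason != _MISSING
    resolved = out[~drop].assign(functional_role=functional[~drop]).reset_index(drop=True)
    excluded = out[drop].assign(exclusion_reason=reason[drop]).reset_index(drop=True)
    return resolved, excluded


def build_master_log(records: pd.DataFrame, encounters: pd.DataFrame) -> pd.DataFrame:
    """Fan out multi-HCP records into same-time events and label shifts.

    A note with an author and a cosigning service yields two events with the
    same ``t_norm``: the author and a same-service attending (the cosigner).
    Events are labeled with shift number (0 = arrival shift, incrementing at
    each 07:00/19:00 boundary) and shift type, and sorted by
    ``(encounter, t_norm, stable input order)``.
    """
    base = records.copy().reset_index(drop=True)
    base["_order"] = np.arange(len(base)) * 2
    cos = base[
        (base["activity_type"] == "note")
        & base["cosigner_service"].fillna(_MISSING).ne(_MISSING)
    ].copy()
    if len(cos):
        cos["hcp_id"] = "cosign::" + cos["cosigner_service"]
        cos["functional_role"] = [
            make_label(s, "attending") for s in cos["cosigner_service"]
        ]
        cos["_order"] = cos["_order"] + 1
    events = pd.concat([base, cos], ignore_index=True)

    arrivals = encounters.set_index("encounter_id")["arrival_clock"]
    arr = pd.to_datetime(arrivals.loc[events["encounter_id"]]).reset_index(drop=True)
    shift_number, shift_type = shifts.shift_labels(arr, events["t_norm"].to_numpy())
    events["shift_number"] = shift_number
    events["shift_type"] = shift_type
    events["segment_id"] = -1
    events = events.sort_values(
        ["encounter_id", "t_norm", "_order"], kind="stable"
    ).reset_index(drop=True)
    keep = EVENT_COLUMNS + [c for c in ("truth_burst_id", "record_id") if c in events.columns]
    return events[keep]


def prepare_master_log(
    records: pd.DataFrame,
    encounters: pd.DataFrame,
    adt: pd.DataFrame,
    roster: pd.DataFrame | None = None,
):
    """Full chain: normalize -> exclude -> infer locations -> resolve roles ->
    master log.  Returns ``(master_log, exclusions)`` where ``exclusions``
    stacks every dropped record with its reason code."""
    normalized, pre = normalize_timestamps(records, encounters, return_excluded=True)
    kept, excluded1 = apply_exclusions(normalized)
    located = infer_locations(kept, adt)
    resolved, excluded2 = resolve_functional_roles(located, roster)
    master = build_master_log(resolved, encounters)
    exclusions = pd.concat([pre, excluded1, excluded2], ignore_index=True)
    return master, exclusions
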