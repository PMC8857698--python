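"""Shared builders and independent oracle implementations for the tests.

Oracles here are deliberately written as direct, brute-force computations so
they stay independent of the library code paths they check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd

_MISSING = ""


def make_records(rows: list[dict]) -> pd.DataFrame:
    """Raw activity-record frame with schema defaults filled in."""
    defaults = {
        "record_id": None,
        "encounter_id": "E0001",
        "timestamp": pd.Timestamp("2017-03-01 08:00:00"),
        "activity_type": "note",
        "hcp_id": "H0001",
        "generic_role": "attending",
        "service": _MISSING,
        "care_location": _MISSING,
        "cosigner_service": _MISSING,
        "system_initiated": False,
        "student": False,
    }
    out = []
    for i, row in enumerate(rows):
        r = dict(defaults, **row)
        if r["record_id"] is None:
            r["record_id"] = f"R{i + 1:04d}"
        out.append(r)
    df = pd.DataFrame(out)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def make_events(rows: list[dict]) -> pd.DataFrame:
    """Master-log event frame with schema defaults filled in."""
    defaults = {
        "encounter_id": "E0001",
        "t_norm": 0.0,
        "activity_type": "note",
        "hcp_id": "H0001",
        "functional_role": "ED_AT",
        "care_location": "ED",
        "shift_number": 0,
        "shift_type": "day",
        "segment_id": 0,
    }
    return pd.DataFrame([dict(defaults, **row) for row in rows])


def make_encounters(rows: list[dict]) -> pd.DataFrame:
    defaults = {
        "encounter_id": "E0001",
        "arrival_clock": pd.Timestamp("2017-03-01 08:00:00"),
        "age_years": 7,
        "sex": "male",
        "activation_level": "bravo",
        "origin": "scene",
        "injury_type": "blunt",
        "iss": 5,
        "gcs": 15,
        "or_admission": False,
        "picu_admission": False,
        "mortality": False,
        "ed_los_minutes": 240.0,
        "hospital_los_minutes": 240.0,
    }
    df = pd.DataFrame([dict(defaults, **row) for row in rows])
    df["arrival_clock"] = pd.to_datetime(df["arrival_clock"])
    return df


# --------------------------------------------------------------------------
# independent oracles


def gvf_oracle(gaps, boundary) -> float:
    """Direct 2-class goodness-of-variance-fit computation."""
    gaps = list(map(float, gaps))
    mean = sum(gaps) / len(gaps)
    total = sum((g - mean) ** 2 for g in gaps)
    within = 0.0
    for cls in ([g for g in gaps if g < boundary], [g for g in gaps if g >= boundary]):
        if cls:
            m = sum(cls) / len(cls)
            within += sum((g - m) ** 2 for g in cls)
    return 1.0 - within / total


def best_break_oracle(gaps, grid=range(30, 125, 5)) -> int:
    """Exhaustive GVF maximization over the grid; ties to the smallest."""
    best_c, best_v = None, -math.inf
    for c in grid:
        v = gvf_oracle(gaps, c)
        if v > best_v:
            best_c, best_v = c, v
    return best_c


def network_counts_oracle(sublog: pd.DataFrame):
    """Exhaustive enumeration of co-present and co-segment shift counts."""
    co_present: dict[tuple[str, str], set] = {}
    co_segment: dict[tuple[str, str], set] = {}
    rows = sublog.to_dict("records")
    shifts = {}
    for r in rows:
        shifts.setdefault((r["encounter_id"], r["shift_number"]), []).append(r)
    for key, rs in shifts.items():
        roles = sorted({r["functional_role"] for r in rs})
        for a, b in itertools.combinations(roles, 2):
            co_present.setdefault((a, b), set()).add(key)
        segments = {}
        for r in rs:
            segments.setdefault(r["segment_id"], set()).add(r["functional_role"])
        for seg_roles in segments.values():
            for a, b in itertools.combinations(sorted(seg_roles), 2):
                co_segment.setdefault((a, b), set()).add(key)
    return (
        {p: len(s) for p, s in co_segment.items()},
        {p: len(s) for p, s in co_present.items()},
    )


def partition_density_oracle(partition, total_edges) -> float:
    """Direct formula: D = (2/M) sum_c m_c (m_c - n_c + 1) / ((n_c-2)(n_c-1))."""
    total = 0.0
    for edges in partition:
        m = len(edges)
        nodes = {u for e in edges for u in e}
        n = len(nodes)
        if n > 2:
            total += m * (m - (n - 1)) / ((n - 2) * (n - 1))
    return 2.0 * total / total_edges if total_edges else 0.0


def max_density_cut_oracle(merges: np.ndarray, leaves, total_edges):
    """Brute-force max partition density over every dendrogram cut.

    Cuts are reconstructed with union-find over the merge list (independent
    of scipy's fcluster).  Returns (best_D, n_clusters_at_best) with ties
    preferring more clusters.
    """
    m = len(leaves)
    heights = [0.0] + sorted({float(h) for h in merges[:, 2]}) if len(merges) else [0.0]
    best = None
    for h in heights:
        parent = list(range(m))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        next_id = m
        cluster_of = {i: i for i in range(m)}
        parent = list(range(2 * m))
        current = {i: i for i in range(m)}  # original cluster id -> uf node
        for row_idx, (a, b, hh, _) in enumerate(merges):
            if hh <= h + 1e-12:
                ra, rb = find(current[int(a)]), find(current[int(b)])
                parent[rb] = ra
                current[m + row_idx] = ra
            else:
                current[m + row_idx] = None
        groups = {}
        for i in range(m):
            groups.setdefault(find(i), []).append(leaves[i])
        d = partition_density_oracle(list(groups.values()), total_edges)
        cand = (round(d, 12), len(groups))
        if best is None or cand > best:
            best = cand
    return best


def jaccard_inclusive(graph, i, j) -> float:
    """Jaccard index of inclusive neighborhoods, for the uniform-weight check."""
    ni = set(graph[i]) | {i}
    nj = set(graph[j]) | {j}
    return len(ni & nj) / len(ni | nj)
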