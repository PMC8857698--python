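"""Collaboration networks from segmented sublogs.

The segmented master log is split into six sublogs — one per (care location,
shift type) — and each sublog yields one weighted undirected network over
functional roles.  Collaboration opportunity is defined per patient-shift:
two roles *could* work together in a (encounter, shift) where both have at
least one event, and *worked closely together* when they share at least one
segment.  The edge weight is

    weight = co_segment_shifts / co_present_shifts,

the fraction of shared shifts in which the pair actually co-segmented,
which normalizes for variation in team composition across encounters.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .roles import LOCATIONS

SHIFT_TYPES = ("day", "night")
SUBLOG_KEYS = tuple((loc, st) for loc in LOCATIONS for st in SHIFT_TYPES)


@dataclass
class SublogSplit:
    sublogs: dict[tuple[str, str], pd.DataFrame]
    n_other_location: int


def split_sublogs(segmented_log: pd.DataFrame) -> SublogSplit:
    """Partition the log into the six (location, shift type) sublogs.

    Events at locations outside ED/FLOOR/PICU are dropped with a count.
    """
    in_scope = segmented_log["care_location"].isin(LOCATIONS)
    n_other = int((~in_scope).sum())
    scoped = segmented_log[in_scope]
    sublogs = {}
    for key in SUBLOG_KEYS:
        loc, st = key
        sublogs[key] = scoped[
            (scoped["care_location"] == loc) & (scoped["shift_type"] == st)
        ].reset_index(drop=True)
    return SublogSplit(sublogs=sublogs, n_other_location=n_other)


@dataclass
class CollabNetwork:
    """Weighted role-role network for one sublog.

    ``graph`` carries per-edge ``co_segment_shifts``, ``co_present_shifts``
    and ``weight``; nodes are functional-role labels.  Roles present in the
    sublog but never co-segmented with anyone are kept as isolated nodes in
    exports but reported separately, since published team diagrams show only
    connected roles.
    """

    key: tuple[str, str]
    graph: nx.Graph
    n_events: int

    @property
    def isolated_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(n for n in self.graph.nodes if self.graph.degree(n) == 0))

    @property
    def n_nodes_connected(self) -> int:
        return self.graph.number_of_nodes() - len(self.isolated_nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "role_a": a,
                "role_b": b,
                "co_segment_shifts": d["co_segment_shifts"],
                "co_present_shifts": d["co_present_shifts"],
                "weight": d["weight"],
            }
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows,
            columns=["role_a", "role_b", "co_segment_shifts", "co_present_shifts", "weight"],
        )

    def write_graphml(self, path) -> Path:
        path = Path(path)
        nx.write_graphml(self.graph, path)
        return path

    def write_edgelist_csv(self, path) -> Path:
        path = Path(path)
        self.edge_frame().to_csv(path, index=False)
        return path


def build_collaboration_network(
    sublog: pd.DataFrame, key: tuple[str, str] = ("ED", "day")
) -> CollabNetwork:
    """Build the working-closely-together network for one sublog.

    For every segment, all pairwise combinations of the distinct roles
    present are marked co-segmented for that (encounter, shift); a pair
    co-segmented several times within one shift still counts once.
    """
    co_present: dict[tuple[str, str], int] = {}
    co_segment: dict[tuple[str, str], int] = {}
    nodes: set[str] = set()

    for (_enc, _shift), grp in sublog.groupby(["encounter_id", "shift_number"], sort=False):
        roles_in_shift = sorted(set(grp["functional_role"]))
        nodes.update(roles_in_shift)
        for pair in combinations(roles_in_shift, 2):
            co_present[pair] = co_present.get(pair, 0) + 1
        seg_pairs: set[tuple[str, str]] = set()
        for _sid, seg in grp.groupby("segment_id", sort=False):
            seg_roles = sorted(set(seg["functional_role"]))
            seg_pairs.update(combinations(seg_roles, 2))
        for pair in seg_pairs:
            co_segment[pair] = co_segment.get(pair, 0) + 1

    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for pair in sorted(co_segment):
        cs = co_segment[pair]
        cp = co_present[pair]
        g.add_edge(*pair, co_segment_shifts=cs, co_present_shifts=cp, weight=cs / cp)
    return CollabNetwork(key=key, graph=g, n_events=len(sublog))
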