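"""Edge-threshold selection by the elbow of the edge-removal curve.

Raising the shared-shift threshold removes spurious edges quickly at first
and then stalls once only stable collaboration remains.  The threshold is
swept over 2..20 on the raw ``co_segment_shifts`` counts, the per-step
number of edges removed is smoothed with LOWESS, and the elbow — the
smallest threshold from which the smoothed removal rate stays below a small
fraction of its peak — is taken as the operating point.  The curve and the
chosen elbow are always exported so the selection can be inspected by eye,
mirroring how such thresholds are usually judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .errors import ContractError
from .network import CollabNetwork


@dataclass
class ThresholdConfig:
    t_min: int = 2
    t_max: int = 20
    #: LOWESS smoothing fraction over the 19 grid points
    lowess_fraction: float = 0.5
    #: "insignificant" = below this fraction of the peak smoothed removal rate
    elbow_epsilon: float = 0.10

    def validate(self) -> None:
        if not 0 < self.lowess_fraction <= 1:
            raise ContractError("lowess_fraction must be in (0, 1]")
        if not 0 < self.elbow_epsilon < 1:
            raise ContractError("elbow_epsilon must be in (0, 1)")
        if self.t_min >= self.t_max:
            raise ContractError("t_min must be below t_max")


@dataclass
class ThresholdCurve:
    thresholds: np.ndarray  # integers t_min..t_max
    edges_remaining: np.ndarray  # edges with co_segment_shifts >= t
    removed_delta: np.ndarray  # edges removed at each increment
    total_edges: int
    singleton_edges: int  # count == 1 edges, removed implicitly at t_min=2
    smoothed_delta: np.ndarray | None = None
    elbow: int | None = None

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "threshold": self.thresholds,
                "edges_remaining": self.edges_remaining,
                "removed_delta": self.removed_delta,
            }
        )
        if self.smoothed_delta is not None:
            df["smoothed_delta"] = self.smoothed_delta
        return df


def sweep_thresholds(network: CollabNetwork, config: ThresholdConfig | None = None) -> ThresholdCurve:
    """Edges-remaining and edges-removed-per-step over the threshold grid.

    Thresholding uses the raw shared-shift count (``co_segment_shifts``),
    not the normalized weight.
    """
    config = config or ThresholdConfig()
    config.validate()
    counts = np.array(
        [d["co_segment_shifts"] for _, _, d in network.graph.edges(data=True)], dtype=int
    )
    thresholds = np.arange(config.t_min, config.t_max + 1)
    total = len(counts)
    remaining = np.array([(counts >= t).sum() for t in thresholds])
    removed = total - remaining
    delta = np.empty_like(removed)
    delta[0] = removed[0]  # applying t_min removes all lower-count edges at once
    delta[1:] = np.diff(removed)
    return ThresholdCurve(
        thresholds=thresholds,
        edges_remaining=remaining,
        removed_delta=delta,
        total_edges=total,
        singleton_edges=int((counts == 1).sum()),
    )


def smooth_curve(curve: ThresholdCurve, config: ThresholdConfig | None = None) -> ThresholdCurve:
    """Locally weighted linear regression of the removal rate, clipped at 0."""
    config = config or ThresholdConfig()
    config.validate()
    if len(curve.thresholds) < 3:
        warnings.warn("fewer than 3 curve points: smoothing skipped, raw delta used", stacklevel=2)
        curve.smoothed_delta = curve.removed_delta.astype(float)
        return curve
    # it=0: plain locally weighted linear regression.  The robustifying
    # iterations of full LOWESS would treat the removal spike at low
    # thresholds as an outlier and flatten exactly the feature the elbow
    # rule needs.
    smoothed = lowess(
        curve.removed_delta.astype(float),
        curve.thresholds.astype(float),
        frac=config.lowess_fraction,
        it=0,
        return_sorted=False,
    )
    curve.smoothed_delta = np.clip(smoothed, 0.0, None)
    return curve


def detect_elbow(curve: ThresholdCurve, config: ThresholdConfig | None = None) -> int:
    """Smallest threshold from which the smoothed removal rate stays
    insignificant (<= epsilon * peak) for all larger thresholds."""
    config = config or ThresholdConfig()
    config.validate()
    if curve.smoothed_delta is None:
        raise ContractError("curve must be smoothed before elbow detection")
    s = np.asarray(curve.smoothed_delta, dtype=float)
    peak = s.max() if len(s) else 0.0
    if peak == 0.0:
        warnings.warn("removal rate identically zero: elbow degenerate at t_min", stacklevel=2)
        curve.elbow = int(curve.thresholds[0])
        return curve.elbow
    suffix_max = np.maximum.accumulate(s[::-1])[::-1]
    ok = suffix_max <= config.elbow_epsilon * peak
    if ok.any():
        curve.elbow = int(curve.thresholds[int(np.argmax(ok))])
    else:
        warnings.warn(
            "removal rate never becomes insignificant: elbow set to t_max", stacklevel=2
        )
        curve.elbow = int(curve.thresholds[-1])
    return curve.elbow


def apply_threshold(network: CollabNetwork, elbow: int) -> CollabNetwork:
    """Keep edges with ``co_segment_shifts >= elbow``; drop isolated nodes.

    Weights are left unchanged; re-applying the same threshold is a no-op.
    """
    g = nx.Graph()
    for a, b, d in network.graph.edges(data=True):
        if d["co_segment_shifts"] >= elbow:
            g.add_edge(a, b, **d)
    return CollabNetwork(key=network.key, graph=g, n_events=network.n_events)


def select_threshold(network: CollabNetwork, config: ThresholdConfig | None = None):
    """Sweep, smooth, detect the elbow and prune in one call.

    Returns ``(pruned_network, curve)``.
    """
    config = config or ThresholdConfig()
    curve = sweep_thresholds(network, config)
    if curve.total_edges == 0:
        raise ContractError("cannot select a threshold on an empty network")
    smooth_curve(curve, config)
    elbow = detect_elbow(curve, config)
    return apply_threshold(network, elbow), curve
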