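"""Cohort statistics, sublog composition, and the end-to-end pipeline.

``compare_cohort`` produces a Table-1-style day/night comparison (Wilcoxon
rank-sum for interval variables, Pearson chi-square without continuity
correction for categorical ones), ``sublog_composition`` profiles activity
types per sublog, and ``run_pipeline`` chains every stage — event-log
preparation, natural-break segmentation, network construction, elbow
thresholding, link-community detection — writing all artifacts plus a
provenance manifest into a run directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__, shifts
from .errors import StageError
from .eventlog import prepare_master_log
from .linkcomm import LinkCommunityResult, detect_link_communities
from .network import SUBLOG_KEYS, CollabNetwork, build_collaboration_network, split_sublogs
from .roles import ACTIVITY_TYPES
from .segmentation import collect_gaps, select_break_interval, segment_shifts
from .synthetic import (
    GeneratorConfig,
    SyntheticStudy,
    generate_study,
    read_raw_dataset,
    write_raw_dataset,
)
from .thresholding import ThresholdConfig, select_threshold

logger = logging.getLogger(__name__)


def percentage(numerator: float, denominator: float, digits: int = 1) -> float:
    """Share of ``numerator`` in ``denominator`` as a percentage, rounded the
    way clinical tables print it (e.g. 272/413 -> 65.9)."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * numerator / denominator, digits)


# --------------------------------------------------------------------------
# Table-1-style cohort comparison

#: (variable, kind) pairs for the default synthetic encounter schema
DEFAULT_COHORT_VARIABLES = [
    ("age_years", "interval"),
    ("sex", "categorical"),
    ("activation_level", "categorical"),
    ("origin", "categorical"),
    ("injury_type", "categorical"),
    ("iss", "interval"),
    ("gcs", "interval"),
    ("ed_los_minutes", "interval"),
    ("hospital_los_minutes", "interval"),
    ("or_admission", "categorical"),
    ("picu_admission", "categorical"),
    ("mortality", "categorical"),
]


@dataclass
class CohortComparison:
    """Day/night comparison of encounter characteristics."""

    table: pd.DataFrame
    group_counts: dict[str, int]
    group_pct: dict[str, float]

    def to_csv(self, path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def _rank_sum_test(day: np.ndarray, night: np.ndarray):
    """Two-sided Wilcoxon rank-sum, normal approximation with tie correction."""
    if len(np.unique(np.concatenate([day, night]))) == 1:
        # all observations identical: no evidence either way
        return 0.0, 1.0
    res = stats.mannwhitneyu(
        day, night, alternative="two-sided", use_continuity=False, method="asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def _chi_square_test(table: np.ndarray):
    """Pearson chi-square without continuity correction; flags sparse cells."""
    res = stats.chi2_contingency(table, correction=False)
    low_expected = bool((res.expected_freq < 5).any())
    return float(res.statistic), float(res.pvalue), low_expected


def _iqr_summary(x: np.ndarray) -> str:
    med = np.median(x)
    q1, q3 = np.percentile(x, [25, 75])
    return f"{med:g} ({q1:g}-{q3:g})"


def compare_cohort(
    encounters: pd.DataFrame, variables=None
) -> CohortComparison:
    """Compare day- vs night-arrival encounters variable by variable.

    Interval variables are summarized as median (IQR) and tested with the
    Wilcoxon rank-sum; categorical variables as n (%) per level and tested
    with Pearson chi-square over the level-by-shift table.  Levels with zero
    total count are dropped with a warning.
    """
    variables = variables if variables is not None else DEFAULT_COHORT_VARIABLES
    arrival_shift = pd.Series(
        shifts.shift_type_of_clock(encounters["arrival_clock"]), index=encounters.index
    )
    day = encounters[arrival_shift == "day"]
    night = encounters[arrival_shift == "night"]
    n_day, n_night, n_all = len(day), len(night), len(encounters)

    rows = []
    for var, kind in variables:
        if kind == "interval":
            stat, p = _rank_sum_test(
                day[var].to_numpy(dtype=float), night[var].to_numpy(dtype=float)
            )
            rows.append(
                {
                    "variable": var,
                    "level": "",
                    "type": kind,
                    "day_summary": _iqr_summary(day[var].to_numpy(dtype=float)),
                    "night_summary": _iqr_summary(night[var].to_numpy(dtype=float)),
                    "test": "wilcoxon_rank_sum",
                    "statistic": stat,
                    "p_value": p,
                    "low_expected_cell": False,
                }
            )
        elif kind == "categorical":
            if isinstance(encounters[var].dtype, pd.CategoricalDtype):
                levels = [str(c) for c in encounters[var].cat.categories]
            else:
                levels = sorted(encounters[var].astype(str).unique())
            counts = []
            kept_levels = []
            for lev in levels:
                c_day = int((day[var].astype(str) == lev).sum())
                c_night = int((night[var].astype(str) == lev).sum())
                if c_day + c_night == 0:
                    warnings.warn(f"{var}={lev}: zero total count, level dropped", stacklevel=2)
                    continue
                counts.append([c_day, c_night])
                kept_levels.append(lev)
            table = np.asarray(counts)
            if len(table) >= 2:
                stat, p, low = _chi_square_test(table)
            else:
                stat, p, low = float("nan"), float("nan"), False
            for lev, (c_day, c_night) in zip(kept_levels, counts):
                rows.append(
                    {
                        "variable": var,
                        "level": lev,
                        "type": kind,
                        "day_summary": f"{c_day} ({percentage(c_day, n_day)})",
                        "night_summary": f"{c_night} ({percentage(c_night, n_night)})",
                        "test": "pearson_chi_square",
                        "statistic": stat,
                        "p_value": p,
                        "low_expected_cell": low,
                    }
                )
        else:
            raise ValueError(f"unknown variable kind: {kind!r}")

    return CohortComparison(
        table=pd.DataFrame(rows),
        group_counts={"day": n_day, "night": n_night},
        group_pct={
            "day": percentage(n_day, n_all),
            "night": percentage(n_night, n_all),
        },
    )


# --------------------------------------------------------------------------
# sublog composition


def sublog_composition(segmented_log: pd.DataFrame) -> pd.DataFrame:
    """Fraction of events per activity type for each of the six sublogs.

    Fractions sum to 1 per non-empty sublog; empty sublogs yield an all-zero
    row with ``n_events`` 0.
    """
    split = split_sublogs(segmented_log)
    rows = []
    for (loc, st), sub in split.sublogs.items():
        n = len(sub)
        row = {"care_location": loc, "shift_type": st, "n_events": n}
        for at in ACTIVITY_TYPES:
            row[at] = (sub["activity_type"] == at).sum() / n if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Either ``dataset_dir`` points at an existing raw dataset (the documented
    CSV dialect) or ``generator`` describes a synthetic study to generate
    in-place.  ``jenks_scope`` chooses whether one break interval is chosen
    globally (the default, keeping day/night networks comparable) or one per
    sublog.
    """

    generator: GeneratorConfig | None = None
    dataset_dir: str | None = None
    jenks_scope: str = "global"  # or "per_sublog"
    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    make_plots: bool = True
    seed: int | None = None  # overrides generator.seed when set

    def resolved_generator(self) -> GeneratorConfig | None:
        if self.generator is None:
            return None
        if self.seed is not None:
            from dataclasses import replace

            return replace(self.generator, seed=self.seed)
        return self.generator

    def to_dict(self) -> dict:
        gen = self.resolved_generator()
        d = {
            "dataset_dir": self.dataset_dir,
            "jenks_scope": self.jenks_scope,
            "threshold": {
                "t_min": self.threshold.t_min,
                "t_max": self.threshold.t_max,
                "lowess_fraction": self.threshold.lowess_fraction,
                "elbow_epsilon": self.threshold.elbow_epsilon,
            },
            "make_plots": self.make_plots,
        }
        if gen is not None:
            gd = {k: v for k, v in vars(gen).items()}
            gd["locations"] = list(gd["locations"])
            for key in ("ground_truth_day", "ground_truth_night"):
                spec_table = gd[key]
                if spec_table is not None:
                    gd[key] = {
                        loc: {
                            "communities": [sorted(c) for c in s.communities],
                            "hubs": sorted(s.hubs),
                        }
                        for loc, s in sorted(spec_table.items())
                    }
            for key in (
                "bursts_per_shift",
                "within_burst_gap_minutes",
                "between_burst_gap_minutes",
                "ed_los_minutes",
                "picu_los_minutes",
                "floor_los_minutes",
            ):
                gd[key] = list(gd[key])
            d["generator"] = gd
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        from .synthetic import CommunitySpec

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = None
        if "generator" in raw and raw["generator"] is not None:
            gd = dict(raw["generator"])
            for key in ("ground_truth_day", "ground_truth_night"):
                if gd.get(key):
                    gd[key] = {
                        loc: CommunitySpec(
                            communities=tuple(frozenset(c) for c in s["communities"]),
                            hubs=frozenset(s.get("hubs", [])),
                        )
                        for loc, s in gd[key].items()
                    }
            for key in (
                "locations",
                "bursts_per_shift",
                "within_burst_gap_minutes",
                "between_burst_gap_minutes",
                "ed_los_minutes",
                "picu_los_minutes",
                "floor_los_minutes",
            ):
                if key in gd:
                    gd[key] = tuple(gd[key])
            gen = GeneratorConfig(**gd)
        thr = ThresholdConfig(**raw.get("threshold", {}))
        return cls(
            generator=gen,
            dataset_dir=raw.get("dataset_dir"),
            jenks_scope=raw.get("jenks_scope", "global"),
            threshold=thr,
            make_plots=raw.get("make_plots", True),
            seed=raw.get("seed"),
        )


@dataclass
class SublogResult:
    key: tuple[str, str]
    n_events: int
    network: CollabNetwork | None = None
    pruned: CollabNetwork | None = None
    threshold: int | None = None
    communities: LinkCommunityResult | None = None
    break_interval: int | None = None  # per-sublog mode only


@dataclass
class PipelineResult:
    out_dir: Path
    study: SyntheticStudy
    master_log: pd.DataFrame
    segmented_log: pd.DataFrame
    break_interval: int | None
    sublogs: dict[tuple[str, str], SublogResult]
    cohort: CohortComparison
    composition: pd.DataFrame
    summary: dict


def _plot_threshold_curve(curve, key, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(curve.thresholds, curve.removed_delta, "o-", color="0.6", label="edges removed")
    if curve.smoothed_delta is not None:
        ax.plot(curve.thresholds, curve.smoothed_delta, "-", color="black", label="LOWESS")
    if curve.elbow is not None:
        ax.axvline(curve.elbow, color="red", label=f"elbow = {curve.elbow}")
    ax.set_xlabel("shared-shift threshold")
    ax.set_ylabel("edges removed per step")
    ax.set_title(f"{key[0]} {key[1]}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)


def run_pipeline(config: PipelineConfig, out_dir) -> PipelineResult:
    """Execute the full chain and write all artifacts under ``out_dir``.

    Identical configuration + seed reproduces byte-identical outputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- input stage -------------------------------------------------------
    gen = config.resolved_generator()
    try:
        if gen is not None:
            study = generate_study(gen)
            write_raw_dataset(study, out_dir / "dataset")
        elif config.dataset_dir:
            study = read_raw_dataset(config.dataset_dir)
        else:
            raise StageError("input", "config must set either generator or dataset_dir")
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive wrap
        raise StageError("input", str(exc)) from exc

    # --- event log ---------------------------------------------------------
    try:
        master, exclusions = prepare_master_log(
            study.records, study.encounters, study.adt, study.roster
        )
    except Exception as exc:
        raise StageError("eventlog", str(exc)) from exc
    logger.info("master log: %d events, %d exclusions", len(master), len(exclusions))
    master.to_csv(out_dir / "master_log.csv", index=False)
    exclusions.to_csv(out_dir / "exclusions.csv", index=False)

    # --- segmentation ------------------------------------------------------
    try:
        if config.jenks_scope == "global":
            selection = select_break_interval(collect_gaps(master))
            segmented, _segments = segment_shifts(master, selection.chosen_interval)
            break_interval = selection.chosen_interval
            per_sublog_intervals = None
            (out_dir / "break_selection.json").write_text(
                json.dumps(
                    {
                        "scope": "global",
                        "grid": list(selection.candidate_grid),
                        "gvf": [round(v, 10) for v in selection.gvf_by_candidate],
                        "chosen_interval": selection.chosen_interval,
                        "degenerate": selection.degenerate,
                    },
                    indent=2,
                    sort_keys=True,
                )
            )
        elif config.jenks_scope == "per_sublog":
            break_interval = None
            per_sublog_intervals = {}
            # segment each sublog with its own interval, then stitch together
            pre_split = split_sublogs(master.assign(segment_id=-1))
            pieces = []
            info = {}
            for key, sub in pre_split.sublogs.items():
                if sub.empty:
                    continue
                sel = select_break_interval(collect_gaps(sub))
                seg, _ = segment_shifts(sub, sel.chosen_interval)
                per_sublog_intervals[key] = sel.chosen_interval
                info["/".join(key)] = sel.chosen_interval
                pieces.append(seg)
            segmented = (
                pd.concat(pieces, ignore_index=True)
                if pieces
                else master.assign(segment_id=-1)
            )
            (out_dir / "break_selection.json").write_text(
                json.dumps(
                    {"scope": "per_sublog", "chosen_intervals": info},
                    indent=2,
                    sort_keys=True,
                )
            )
        else:
            raise StageError("segmentation", f"unknown jenks_scope {config.jenks_scope!r}")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("segmentation", str(exc)) from exc
    segmented.to_csv(out_dir / "segmented_log.csv", index=False)

    # --- per-sublog networks -> thresholds -> communities -------------------
    split = split_sublogs(segmented)
    results: dict[tuple[str, str], SublogResult] = {}
    for key in SUBLOG_KEYS:
        sub = split.sublogs[key]
        res = SublogResult(key=key, n_events=len(sub))
        if per_sublog_intervals is not None:
            res.break_interval = per_sublog_intervals.get(key)
        results[key] = res
        if sub.empty:
            continue
        name = f"{key[0]}_{key[1]}".lower()
        try:
            net = build_collaboration_network(sub, key)
            res.network = net
            net.write_graphml(out_dir / f"network_{name}.graphml")
            net.write_edgelist_csv(out_dir / f"edges_{name}.csv")
            if net.n_edges == 0:
                continue
            pruned, curve = select_threshold(net, config.threshold)
            res.pruned = pruned
            res.threshold = curve.elbow
            curve.frame().to_csv(out_dir / f"threshold_curve_{name}.csv", index=False)
            if config.make_plots:
                _plot_threshold_curve(curve, key, out_dir / f"threshold_curve_{name}.png")
            pruned.write_graphml(out_dir / f"network_{name}_pruned.graphml")
            if pruned.n_edges:
                res.communities = detect_link_communities(pruned)
                (out_dir / f"communities_{name}.json").write_text(
                    json.dumps(res.communities.to_dict(), indent=2, sort_keys=True)
                )
        except Exception as exc:
            raise StageError(f"network:{name}", str(exc)) from exc

    # --- reporting ---------------------------------------------------------
    try:
        cohort = compare_cohort(study.encounters)
        cohort.to_csv(out_dir / "table1.csv")
        composition = sublog_composition(segmented)
        composition.to_csv(out_dir / "composition.csv", index=False)
    except Exception as exc:
        raise StageError("reporting", str(exc)) from exc

    summary = {
        "n_encounters": len(study.encounters),
        "arrival_counts": cohort.group_counts,
        "arrival_pct": cohort.group_pct,
        "n_raw_records": len(study.records),
        "n_master_events": len(master),
        "n_excluded": len(exclusions),
        "exclusion_reasons": exclusions["exclusion_reason"].value_counts().to_dict()
        if len(exclusions)
        else {},
        "break_interval": break_interval,
        "jenks_scope": config.jenks_scope,
        "n_events_other_location": split.n_other_location,
        "sublogs": {},
    }
    for key, res in results.items():
        name = f"{key[0]}_{key[1]}".lower()
        entry: dict = {"n_events": res.n_events}
        if res.break_interval is not None:
            entry["break_interval"] = res.break_interval
        if res.network is not None:
            entry["n_nodes_total"] = res.network.graph.number_of_nodes()
            entry["n_nodes_connected"] = res.network.n_nodes_connected
            entry["n_edges"] = res.network.n_edges
        if res.threshold is not None:
            entry["threshold"] = res.threshold
        if res.pruned is not None:
            entry["n_nodes_pruned"] = res.pruned.graph.number_of_nodes()
            entry["n_edges_pruned"] = res.pruned.n_edges
        if res.communities is not None:
            entry["n_communities"] = len(res.communities.communities)
            entry["partition_density"] = round(res.communities.partition_density_value, 6)
            entry["roles_in_all_communities"] = list(res.communities.roles_in_all_communities())
        summary["sublogs"][name] = entry

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))

    config_json = json.dumps(config.to_dict(), indent=2, sort_keys=True)
    manifest = {
        "carenet_version": __version__,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": gen.seed if gen is not None else None,
        "versions": _library_versions(),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return PipelineResult(
        out_dir=out_dir,
        study=study,
        master_log=master,
        segmented_log=segmented,
        break_interval=break_interval,
        sublogs=results,
        cohort=cohort,
        composition=composition,
        summary=summary,
    )


def _library_versions() -> dict[str, str]:
    import networkx
    import scipy
    import statsmodels

    return {
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }
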