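"""Synthetic EHR event-log generator with planted team structure.

No public pediatric-trauma EHR extract exists, so every downstream stage is
exercised against synthetic cohorts whose *collaboration structure is known
by construction*: each (care location, shift type) carries a community
specification — sets of functional roles that document together in bursts,
plus optional hub roles that join every burst.  Day shifts default to a
single merged community per location while nights split into specialty
communities sharing the general-pediatric-surgery attending/resident hubs,
emulating the diurnal contrast the pipeline is designed to detect.

The generator emits *raw* activity records (absolute wall-clock timestamps,
unresolved services, student/system rows, multi-author notes), so the
eventlog module has to perform the full normalization/resolution chain.
Records carry a ``truth_burst_id`` annotation column that the pipeline
ignores; tests use it to compare recovered segments against planted bursts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, GenerationError
from .roles import LOCATION_SERVICE, LOCATIONS, parse_label
from .shifts import DAY_START_MINUTE, SHIFT_MINUTES, global_shift_index

_MISSING = ""  # empty string encodes "missing" in optional string columns

RECORD_COLUMNS = [
    "record_id",
    "encounter_id",
    "timestamp",
    "activity_type",
    "hcp_id",
    "generic_role",
    "service",
    "care_location",
    "cosigner_service",
    "system_initiated",
    "student",
    "truth_burst_id",
]

ENCOUNTER_COLUMNS = [
    "encounter_id",
    "arrival_clock",
    "age_years",
    "sex",
    "activation_level",
    "origin",
    "injury_type",
    "iss",
    "gcs",
    "or_admission",
    "picu_admission",
    "mortality",
    "ed_los_minutes",
    "hospital_los_minutes",
]


@dataclass(frozen=True)
class CommunitySpec:
    """Planted communities for one (location, shift type).

    ``communities`` lists the non-hub role sets; ``hubs`` are added to every
    burst of every community, so hub roles belong to all communities of the
    spec by construction.
    """

    communities: tuple[frozenset[str], ...]
    hubs: frozenset[str] = frozenset()

    def all_roles(self) -> frozenset[str]:
        roles: set[str] = set(self.hubs)
        for c in self.communities:
            roles |= c
        return frozenset(roles)

    def community_roles(self, idx: int) -> frozenset[str]:
        return self.communities[idx] | self.hubs


@dataclass
class GroundTruth:
    """Planted community structure per shift type and location."""

    day: dict[str, CommunitySpec]
    night: dict[str, CommunitySpec]

    def spec_for(self, location: str, shift_type: str) -> CommunitySpec | None:
        table = self.day if shift_type == "day" else self.night
        return table.get(location)

    def planted_pairs(self, location: str, shift_type: str) -> set[tuple[str, str]]:
        """All role pairs that should form edges: within-community plus hub pairs."""
        spec = self.spec_for(location, shift_type)
        if spec is None:
            return set()
        pairs: set[tuple[str, str]] = set()
        for i in range(len(spec.communities)):
            roles = sorted(spec.community_roles(i))
            for a_idx in range(len(roles)):
                for b_idx in range(a_idx + 1, len(roles)):
                    pairs.add((roles[a_idx], roles[b_idx]))
        return pairs

    def cross_pairs(self, location: str, shift_type: str) -> set[tuple[str, str]]:
        """Role pairs from different communities, excluding hub-involved pairs."""
        spec = self.spec_for(location, shift_type)
        if spec is None:
            return set()
        roles = sorted(spec.all_roles() - spec.hubs)
        planted = self.planted_pairs(location, shift_type)
        return {
            (roles[i], roles[j])
            for i in range(len(roles))
            for j in range(i + 1, len(roles))
            if (roles[i], roles[j]) not in planted
        }

    def pair_labels(self, location: str, shift_type: str) -> dict[tuple[str, str], list[int]]:
        """Community indices for every planted pair (hub pairs map to all)."""
        spec = self.spec_for(location, shift_type)
        if spec is None:
            return {}
        labels: dict[tuple[str, str], list[int]] = {}
        for idx in range(len(spec.communities)):
            roles = sorted(spec.community_roles(idx))
            for i in range(len(roles)):
                for j in range(i + 1, len(roles)):
                    labels.setdefault((roles[i], roles[j]), []).append(idx)
        return labels

    def to_dict(self) -> dict:
        def enc(table: dict[str, CommunitySpec]) -> dict:
            return {
                loc: {
                    "communities": [sorted(c) for c in spec.communities],
                    "hubs": sorted(spec.hubs),
                }
                for loc, spec in sorted(table.items())
            }

        return {"day": enc(self.day), "night": enc(self.night)}

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        def dec(table: dict) -> dict[str, CommunitySpec]:
            return {
                loc: CommunitySpec(
                    communities=tuple(frozenset(c) for c in spec["communities"]),
                    hubs=frozenset(spec["hubs"]),
                )
                for loc, spec in table.items()
            }

        return cls(day=dec(d["day"]), night=dec(d["night"]))


def default_ground_truth(locations=LOCATIONS) -> GroundTruth:
    """Default planted structure mimicking the diurnal pattern of a level I
    pediatric trauma center: one merged day community per location; at night,
    five specialty communities in the ED and on the floor, sharing the
    general-pediatric-surgery (GPS) attending + resident as hubs, and a single
    community in the PICU."""
    gps_hubs = frozenset({"GPS_AT", "GPS_R"})
    night = {
        "ED": CommunitySpec(
            communities=(
                frozenset({"ED_AT", "ED_R", "ED_RN", "ED_Rad_Tech"}),
                frozenset({"Neurosurg_AT", "Neurosurg_R"}),
                frozenset({"Ortho_AT", "Ortho_R"}),
                frozenset({"Anes_AT", "Anes_R"}),
                frozenset({"ED_NP", "ED_RN_Tech"}),
            ),
            hubs=gps_hubs,
        ),
        "FLOOR": CommunitySpec(
            communities=(
                frozenset({"Floor_RN", "Floor_NP", "Floor_RN_Tech", "Floor_Pharm"}),
                frozenset({"Neurosurg_AT", "Neurosurg_R"}),
                frozenset({"Ortho_AT", "Ortho_R"}),
                frozenset({"Peds_AT", "Peds_R"}),
                frozenset({"PPS_AT", "PPS_R"}),
            ),
            hubs=gps_hubs,
        ),
        "PICU": CommunitySpec(
            communities=(
                frozenset(
                    {
                        "PICU_AT",
                        "PICU_F",
                        "PICU_RN",
                        "PICU_R",
                        "GPS_AT",
                        "GPS_R",
                        "Neurosurg_AT",
                        "Neurosurg_R",
                    }
                ),
            ),
        ),
    }
    day = {
        "ED": CommunitySpec(
            communities=(
                night["ED"].all_roles() | frozenset({"ED_SW", "ED_CLS"}),
            ),
        ),
        "FLOOR": CommunitySpec(
            communities=(
                night["FLOOR"].all_roles()
                | frozenset({"Floor_SW", "Floor_CM", "Floor_CLS", "Floor_OT", "Floor_DT"}),
            ),
        ),
        "PICU": CommunitySpec(
            communities=(
                night["PICU"].all_roles()
                | frozenset({"PICU_SW", "PICU_CM", "PICU_OT", "PICU_DT"}),
            ),
        ),
    }
    keep = set(locations)
    return GroundTruth(
        day={k: v for k, v in day.items() if k in keep},
        night={k: v for k, v in night.items() if k in keep},
    )


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the study design the pipeline targets: 413 encounters
    over one year, 65.9% arriving during day shifts, bursty within-shift
    documentation with quiet gaps well above the natural-break scale, and a
    small background of unresolved-service, student/system and spurious
    one-off records.
    """

    n_encounters: int = 413
    day_fraction: float = 0.659
    locations: tuple[str, ...] = LOCATIONS
    ground_truth_day: dict[str, CommunitySpec] | None = None
    ground_truth_night: dict[str, CommunitySpec] | None = None
    roster_spec: dict[str, int] | None = None
    bursts_per_shift: tuple[int, int] = (1, 3)
    within_burst_gap_minutes: tuple[float, float] = (1.0, 10.0)
    between_burst_gap_minutes: tuple[float, float] = (150.0, 240.0)
    noise_coocc_rate: float = 0.1
    max_noise_pair_shifts: int = 3
    unresolved_role_fraction: float = 0.05
    student_system_fraction: float = 0.05
    picu_admission_prob: float = 0.17
    floor_admission_prob: float = 0.45
    picu_to_floor_prob: float = 0.7
    ed_los_minutes: tuple[float, float] = (150.0, 360.0)
    picu_los_minutes: tuple[float, float] = (1080.0, 2880.0)
    floor_los_minutes: tuple[float, float] = (720.0, 3600.0)
    start_date: str = "2017-01-01"
    study_days: int = 365
    seed: int = 0

    def ground_truth(self) -> GroundTruth:
        default = default_ground_truth(self.locations)
        return GroundTruth(
            day=self.ground_truth_day if self.ground_truth_day is not None else default.day,
            night=self.ground_truth_night
            if self.ground_truth_night is not None
            else default.night,
        )

    def validate(self) -> None:
        if self.n_encounters <= 0:
            raise ConfigurationError("n_encounters must be positive")
        for name in (
            "day_fraction",
            "noise_coocc_rate",
            "unresolved_role_fraction",
            "student_system_fraction",
            "picu_admission_prob",
            "floor_admission_prob",
            "picu_to_floor_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.unresolved_role_fraction + self.student_system_fraction >= 0.5:
            raise ConfigurationError(
                "unresolved_role_fraction + student_system_fraction too large"
            )
        if not set(self.locations) <= set(LOCATIONS):
            raise ConfigurationError(f"locations must be a subset of {LOCATIONS}")
        if "ED" not in self.locations:
            raise ConfigurationError("locations must include ED (encounters arrive there)")
        lo, hi = self.within_burst_gap_minutes
        blo, bhi = self.between_burst_gap_minutes
        if not (0 <= lo <= hi):
            raise ConfigurationError("within_burst_gap_minutes must be a valid support")
        if not (0 <= blo <= bhi):
            raise ConfigurationError("between_burst_gap_minutes must be a valid support")
        if hi >= blo:
            raise ConfigurationError(
                "within_burst_gap_minutes support must lie strictly below "
                "between_burst_gap_minutes support"
            )
        if self.bursts_per_shift[0] < 0 or self.bursts_per_shift[0] > self.bursts_per_shift[1]:
            raise ConfigurationError("bursts_per_shift must be a valid (lo, hi) range")
        # role labels must parse; hub roles are in every community by construction
        truth = self.ground_truth()
        for table in (truth.day, truth.night):
            for spec in table.values():
                for label in spec.all_roles():
                    try:
                        parse_label(label)
                    except ValueError as exc:
                        raise ConfigurationError(str(exc)) from exc


@dataclass
class SyntheticStudy:
    """A generated cohort: encounter table, HCP roster, ADT timelines, raw
    activity records and the planted ground truth."""

    encounters: pd.DataFrame
    roster: pd.DataFrame
    adt: pd.DataFrame
    records: pd.DataFrame
    truth: GroundTruth
    config: GeneratorConfig | None = None

    def equals(self, other: "SyntheticStudy") -> bool:
        return (
            self.encounters.equals(other.encounters)
            and self.roster.equals(other.roster)
            and self.adt.equals(other.adt)
            and self.records.equals(other.records)
            and self.truth.to_dict() == other.truth.to_dict()
        )


# --------------------------------------------------------------------------
# cohort generation


def _sample_age(rng: np.random.Generator, is_day: bool) -> int:
    # day arrivals skew younger (median ~7y) than night (~10y)
    scale = 3.5 if is_day else 5.0
    return int(np.clip(round(rng.gamma(2.0, scale)), 0, 18))


_ACTIVATION_LEVELS = ("alpha", "bravo", "critical_transfer")
_ACTIVATION_P = {"day": (0.096, 0.816, 0.088), "night": (0.036, 0.702, 0.262)}
_ORIGINS = ("scene", "transfer", "other")
_ORIGIN_P = {"day": (0.901, 0.007, 0.092), "night": (0.723, 0.270, 0.007)}
_INJURY_TYPES = ("blunt", "penetrating", "other")
_INJURY_P = {"day": (0.952, 0.018, 0.030), "night": (0.894, 0.078, 0.028)}
_MALE_P = {"day": 0.677, "night": 0.589}
_OR_P = {"day": 0.151, "night": 0.156}
_MORTALITY_P = {"day": 0.026, "night": 0.014}


def generate_cohort(config: GeneratorConfig) -> SyntheticStudy:
    """Generate encounters, roster and ADT timelines (no activity records yet)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = config.ground_truth()
    start = pd.Timestamp(config.start_date)

    enc_rows = []
    adt_rows = []
    for i in range(config.n_encounters):
        enc_id = f"E{i + 1:04d}"
        is_day = rng.random() < config.day_fraction
        day_offset = int(rng.integers(0, config.study_days))
        if is_day:
            minute = int(rng.integers(DAY_START_MINUTE, DAY_START_MINUTE + SHIFT_MINUTES))
        else:
            minute = int(
                rng.integers(
                    DAY_START_MINUTE + SHIFT_MINUTES,
                    DAY_START_MINUTE + 2 * SHIFT_MINUTES,
                )
            )
        arrival = start + pd.Timedelta(days=day_offset, minutes=minute)
        shift = "day" if is_day else "night"

        age = _sample_age(rng, is_day)
        sex = "male" if rng.random() < _MALE_P[shift] else "female"
        activation = str(rng.choice(_ACTIVATION_LEVELS, p=_ACTIVATION_P[shift]))
        origin = str(rng.choice(_ORIGINS, p=_ORIGIN_P[shift]))
        injury = str(rng.choice(_INJURY_TYPES, p=_INJURY_P[shift]))
        iss = int(np.clip(round(rng.gamma(1.5, 4.0)), 1, 75))
        gcs = 15 if rng.random() < 0.9 else int(rng.integers(3, 15))
        or_admission = bool(rng.random() < _OR_P[shift])
        mortality = bool(rng.random() < _MORTALITY_P[shift])

        ed_los = float(round(rng.uniform(*config.ed_los_minutes)))
        picu = "PICU" in config.locations and rng.random() < config.picu_admission_prob
        timeline = [("ED", 0.0, ed_los)]
        t = ed_los
        if picu:
            picu_los = float(round(rng.uniform(*config.picu_los_minutes)))
            timeline.append(("PICU", t, t + picu_los))
            t += picu_los
            if "FLOOR" in config.locations and rng.random() < config.picu_to_floor_prob:
                floor_los = float(round(rng.uniform(*config.floor_los_minutes)))
                timeline.append(("FLOOR", t, t + floor_los))
                t += floor_los
        elif "FLOOR" in config.locations and rng.random() < config.floor_admission_prob:
            floor_los = float(round(rng.uniform(*config.floor_los_minutes)))
            timeline.append(("FLOOR", t, t + floor_los))
            t += floor_los

        enc_rows.append(
            {
                "encounter_id": enc_id,
                "arrival_clock": arrival,
                "age_years": age,
                "sex": sex,
                "activation_level": activation,
                "origin": origin,
                "injury_type": injury,
                "iss": iss,
                "gcs": gcs,
                "or_admission": or_admission,
                "picu_admission": picu,
                "mortality": mortality,
                "ed_los_minutes": ed_los,
                "hospital_los_minutes": t,
            }
        )
        for loc, s, e in timeline:
            adt_rows.append(
                {
                    "encounter_id": enc_id,
                    "location": loc,
                    "start_minute": s,
                    "end_minute": e,
                }
            )

    encounters = pd.DataFrame(enc_rows, columns=ENCOUNTER_COLUMNS)
    adt = pd.DataFrame(adt_rows, columns=["encounter_id", "location", "start_minute", "end_minute"])
    roster = _build_roster(config, truth)
    records = pd.DataFrame(columns=RECORD_COLUMNS)
    return SyntheticStudy(
        encounters=encounters,
        roster=roster,
        adt=adt,
        records=_finalize_records(records),
        truth=truth,
        config=config,
    )


def _build_roster(config: GeneratorConfig, truth: GroundTruth) -> pd.DataFrame:
    labels: set[str] = set()
    for table in (truth.day, truth.night):
        for spec in table.values():
            labels |= spec.all_roles()
    spec_counts = dict(config.roster_spec or {})
    missing = set(spec_counts) - labels
    if config.roster_spec is not None and not labels <= set(spec_counts):
        raise ConfigurationError(
            "roster_spec must cover every role named in the ground-truth specs; "
            f"missing {sorted(labels - set(spec_counts))}"
        )
    if missing:
        labels |= missing

    rows = []
    idx = 1
    for label in sorted(labels):
        fr = parse_label(label)
        for _ in range(spec_counts.get(label, 1)):
            rows.append(
                {
                    "hcp_id": f"H{idx:04d}",
                    "generic_role": fr.generic_role,
                    "true_service": fr.service,
                    "resolvable": True,
                    "kind": "planted",
                }
            )
            idx += 1
    # HCPs whose service can never be recovered: residents who never author
    # cosigned notes, and attendings with no service evidence anywhere.
    for role in ("resident", "resident", "attending", "attending"):
        rows.append(
            {
                "hcp_id": f"U{idx:04d}",
                "generic_role": role,
                "true_service": _MISSING,
                "resolvable": False,
                "kind": "unresolved",
            }
        )
        idx += 1
    for role in ("medical_student", "nursing_student"):
        rows.append(
            {
                "hcp_id": f"S{idx:04d}",
                "generic_role": role,
                "true_service": _MISSING,
                "resolvable": False,
                "kind": "student",
            }
        )
        idx += 1
    rows.append(
        {
            "hcp_id": "SYSTEM",
            "generic_role": "system",
            "true_service": _MISSING,
            "resolvable": False,
            "kind": "system",
        }
    )
    return pd.DataFrame(rows, columns=["hcp_id", "generic_role", "true_service", "resolvable", "kind"])


# --------------------------------------------------------------------------
# activity-record generation


class _RecordEmitter:
    """Accumulates raw activity records with deterministic bookkeeping."""

    def __init__(self, config: GeneratorConfig, roster: pd.DataFrame, rng: np.random.Generator):
        self.config = config
        self.rng = rng
        self.rows: list[dict] = []
        self.seen_note: set[tuple[str, str]] = set()  # (hcp_id, encounter_id)
        self.burst_counter = 0
        # role label -> list of planted hcp_ids
        self.role_hcps: dict[str, list[str]] = {}
        planted = roster[roster["kind"] == "planted"]
        for _, r in planted.iterrows():
            from .roles import make_label

            self.role_hcps.setdefault(make_label(r["true_service"], r["generic_role"]), []).append(
                r["hcp_id"]
            )
        self.unresolved = roster[roster["kind"] == "unresolved"].to_dict("records")
        self.students = roster[roster["kind"] == "student"].to_dict("records")
        denom = 1.0 - config.unresolved_role_fraction - config.student_system_fraction
        self.p_unresolved = config.unresolved_role_fraction / denom
        self.p_student_system = config.student_system_fraction / denom

    def pick_hcp(self, label: str) -> str:
        hcps = self.role_hcps[label]
        if len(hcps) == 1:
            return hcps[0]
        return hcps[int(self.rng.integers(len(hcps)))]

    def emit_planted(self, enc_id: str, arrival: pd.Timestamp, t: float, label: str, loc: str, burst_id: int):
        fr = parse_label(label)
        hcp = self.pick_hcp(label)
        rng = self.rng
        service = _MISSING
        cosigner = _MISSING
        if fr.generic_role in ("resident", "radiology_technician"):
            first = (hcp, enc_id) not in self.seen_note
            if first or rng.random() < 0.5:
                activity = "note"
                cosigner = fr.service  # cosigned by the service attending
                self.seen_note.add((hcp, enc_id))
            else:
                activity = "procedure_order" if fr.generic_role == "radiology_technician" else "medication_order"
        elif fr.generic_role in ("attending", "fellow"):
            u = rng.random()
            if u < 0.6:
                activity = "note"
                service = fr.service  # note metadata includes the author's service
            elif u < 0.8:
                activity = "procedure_order"
            else:
                activity = "medication_order"
        elif fr.generic_role in ("nurse", "nurse_practitioner", "nurse_technician"):
            activity = "flowsheet" if rng.random() < 0.7 else "medication_admin"
        else:  # allied HCPs
            activity = "flowsheet" if rng.random() < 0.5 else "note"
        care_location = loc if activity in ("procedure_order", "medication_order", "medication_admin") else _MISSING
        self._append(enc_id, arrival, t, activity, hcp, fr.generic_role, service, care_location, cosigner, False, False, burst_id)
        self._maybe_emit_extras(enc_id, arrival, t, loc, burst_id)

    def _maybe_emit_extras(self, enc_id: str, arrival: pd.Timestamp, t: float, loc: str, burst_id: int):
        rng = self.rng
        if rng.random() < self.p_unresolved:
            h = self.unresolved[int(rng.integers(len(self.unresolved)))]
            te = t + rng.uniform(0.2, 1.0)
            if h["generic_role"] == "resident":
                # orders only -> no cosigned notes -> service unresolvable
                self._append(enc_id, arrival, te, "medication_order", h["hcp_id"], "resident", _MISSING, loc, _MISSING, False, False, burst_id)
            else:
                # notes without service metadata
                self._append(enc_id, arrival, te, "note", h["hcp_id"], "attending", _MISSING, _MISSING, _MISSING, False, False, burst_id)
        if rng.random() < self.p_student_system:
            te = t + rng.uniform(0.2, 1.0)
            if rng.random() < 0.5:
                h = self.students[int(rng.integers(len(self.students)))]
                self._append(enc_id, arrival, te, "note", h["hcp_id"], h["generic_role"], _MISSING, _MISSING, _MISSING, False, True, burst_id)
            else:
                self._append(enc_id, arrival, te, "flowsheet", "SYSTEM", "system", _MISSING, _MISSING, _MISSING, True, False, burst_id)

    def _append(self, enc_id, arrival, t, activity, hcp, generic_role, service, care_location, cosigner, system, student, burst_id):
        ts = arrival + pd.Timedelta(seconds=round(t * 60.0))
        self.rows.append(
            {
                "record_id": f"R{len(self.rows) + 1:07d}",
                "encounter_id": enc_id,
                "timestamp": ts,
                "activity_type": activity,
                "hcp_id": hcp,
                "generic_role": generic_role,
                "service": service,
                "care_location": care_location,
                "cosigner_service": cosigner,
                "system_initiated": system,
                "student": student,
                "truth_burst_id": burst_id,
            }
        )


def generate_activity_records(study: SyntheticStudy, config: GeneratorConfig) -> SyntheticStudy:
    """Populate ``study.records`` with bursty, planted-community activity.

    Within each shift that an encounter spends at a location, a small number
    of bursts are generated; each burst activates one planted community (plus
    hubs) whose roles all document within short within-burst gaps, while
    consecutive bursts are separated by long quiet gaps.  Spurious one-off
    cross-community pairings, unresolved-service records and student/system
    records are sprinkled in at configured rates.
    """
    config.validate()
    if study.encounters.empty:
        raise GenerationError("cohort not generated: encounters table is empty")
    truth = study.truth
    # every ground-truth role must be represented in the roster
    from .roles import make_label

    roster_labels = {
        make_label(r["true_service"], r["generic_role"])
        for _, r in study.roster[study.roster["kind"] == "planted"].iterrows()
    }
    needed: set[str] = set()
    for table in (truth.day, truth.night):
        for spec in table.values():
            needed |= spec.all_roles()
    if not needed <= roster_labels:
        raise GenerationError(
            f"ground-truth roles absent from roster: {sorted(needed - roster_labels)}"
        )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    emitter = _RecordEmitter(config, study.roster, rng)
    w_lo, w_hi = config.within_burst_gap_minutes
    b_lo, b_hi = config.between_burst_gap_minutes

    # pre-compute noise candidate pairs per (location, shift_type); resident
    # and rad-tech roles are excluded because their notes fan out a cosigning
    # attending, which would create uncapped attending-side cross pairs
    noise_pools: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for shift_type in ("day", "night"):
        table = truth.day if shift_type == "day" else truth.night
        for loc in table:
            pairs = sorted(
                (a, b)
                for (a, b) in truth.cross_pairs(loc, shift_type)
                if parse_label(a).generic_role not in ("resident", "radiology_technician")
                and parse_label(b).generic_role not in ("resident", "radiology_technician")
            )
            noise_pools[(loc, shift_type)] = pairs
    noise_counts: dict[tuple[str, str, str, str], int] = {}

    adt_by_enc = dict(tuple(study.adt.groupby("encounter_id", sort=False)))

    for _, enc in study.encounters.iterrows():
        enc_id = enc["encounter_id"]
        arrival = enc["arrival_clock"]
        g_arrival = int(global_shift_index(arrival))
        arrival_abs = (arrival - pd.Timestamp("2000-01-01")).total_seconds() / 60.0
        last_event_in_shift: dict[int, float] = {}

        timeline = adt_by_enc.get(enc_id)
        if timeline is None:
            continue
        for _, interval in timeline.iterrows():
            loc = interval["location"]
            s, e = float(interval["start_minute"]), float(interval["end_minute"])
            g_first = int(math.floor((arrival_abs + s - DAY_START_MINUTE) / SHIFT_MINUTES))
            g_last = int(math.floor((arrival_abs + e - 1e-9 - DAY_START_MINUTE) / SHIFT_MINUTES))
            for g in range(g_first, g_last + 1):
                shift_type = "day" if g % 2 == 0 else "night"
                spec = truth.spec_for(loc, shift_type)
                if spec is None or not spec.communities:
                    continue
                shift_start = g * SHIFT_MINUTES + DAY_START_MINUTE - arrival_abs
                w0 = max(s, shift_start)
                w1 = min(e, shift_start + SHIFT_MINUTES)
                if w1 - w0 < 30.0:
                    continue
                shift_no = g - g_arrival
                n_bursts = int(rng.integers(config.bursts_per_shift[0], config.bursts_per_shift[1] + 1))
                cursor = w0 + rng.uniform(0.0, 30.0)
                if shift_no in last_event_in_shift:
                    cursor = max(cursor, last_event_in_shift[shift_no] + rng.uniform(b_lo, b_hi))
                for _b in range(n_bursts):
                    cidx = int(rng.integers(len(spec.communities)))
                    roles = sorted(spec.community_roles(cidx))
                    span = (len(roles) - 1) * w_hi
                    if cursor + span > w1:
                        break
                    order = list(roles)
                    rng.shuffle(order)
                    burst_id = emitter.burst_counter
                    emitter.burst_counter += 1
                    t = cursor
                    for j, label in enumerate(order):
                        if j:
                            t += rng.uniform(w_lo, w_hi)
                        emitter.emit_planted(enc_id, arrival, t, label, loc, burst_id)
                    last_event_in_shift[shift_no] = t
                    cursor = t + rng.uniform(b_lo, b_hi)
                # spurious one-off pairing, capped per pair so cross-community
                # co-occurrence stays in the pruned regime
                pool = noise_pools.get((loc, shift_type), [])
                if pool and len(spec.communities) >= 2 and rng.random() < config.noise_coocc_rate:
                    available = [
                        p
                        for p in pool
                        if noise_counts.get((loc, shift_type) + p, 0) < config.max_noise_pair_shifts
                    ]
                    if available and cursor + w_hi <= w1:
                        a, b = available[int(rng.integers(len(available)))]
                        burst_id = emitter.burst_counter
                        emitter.burst_counter += 1
                        emitter.emit_planted(enc_id, arrival, cursor, a, loc, burst_id)
                        t2 = cursor + rng.uniform(w_lo, w_hi)
                        emitter.emit_planted(enc_id, arrival, t2, b, loc, burst_id)
                        noise_counts[(loc, shift_type, a, b)] = (
                            noise_counts.get((loc, shift_type, a, b), 0) + 1
                        )
                        last_event_in_shift[shift_no] = t2
                        cursor = t2 + rng.uniform(b_lo, b_hi)

    records = pd.DataFrame(emitter.rows, columns=RECORD_COLUMNS)
    return replace(study, records=_finalize_records(records))


def _finalize_records(records: pd.DataFrame) -> pd.DataFrame:
    records = records.copy()
    for col in ("service", "care_location", "cosigner_service", "generic_role", "hcp_id"):
        records[col] = records[col].astype(str) if len(records) else records[col].astype(object)
    records["system_initiated"] = records["system_initiated"].astype(bool)
    records["student"] = records["student"].astype(bool)
    records["truth_burst_id"] = records["truth_burst_id"].astype(np.int64) if len(records) else records["truth_burst_id"].astype(np.int64)
    records["timestamp"] = pd.to_datetime(records["timestamp"])
    return records


def generate_study(config: GeneratorConfig) -> SyntheticStudy:
    """Convenience wrapper: cohort + activity records in one call."""
    return generate_activity_records(generate_cohort(config), config)


# --------------------------------------------------------------------------
# on-disk dialect (RFC-4180 CSV, ISO-8601 timestamps, UTF-8; '' = missing)


def write_raw_dataset(study: SyntheticStudy, directory) -> dict[str, Path]:
    """Write encounters.csv / roster.csv / adt.csv / records.csv / truth.json.

    The dialect round-trips losslessly through :func:`read_raw_dataset`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    enc = study.encounters.copy()
    enc["arrival_clock"] = enc["arrival_clock"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    paths["encounters"] = directory / "encounters.csv"
    enc.to_csv(paths["encounters"], index=False)

    paths["roster"] = directory / "roster.csv"
    study.roster.to_csv(paths["roster"], index=False)

    paths["adt"] = directory / "adt.csv"
    study.adt.to_csv(paths["adt"], index=False)

    rec = study.records.copy()
    if len(rec):
        rec["timestamp"] = rec["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    paths["records"] = directory / "records.csv"
    rec.to_csv(paths["records"], index=False)

    paths["truth"] = directory / "truth.json"
    paths["truth"].write_text(json.dumps(study.truth.to_dict(), indent=2, sort_keys=True))
    return paths


def read_raw_dataset(directory) -> SyntheticStudy:
    """Read a dataset written by :func:`write_raw_dataset`."""
    directory = Path(directory)
    encounters = pd.read_csv(
        directory / "encounters.csv",
        parse_dates=["arrival_clock"],
        dtype={"encounter_id": str},
    )
    for col in ("or_admission", "picu_admission", "mortality"):
        encounters[col] = encounters[col].astype(bool)
    encounters["age_years"] = encounters["age_years"].astype(np.int64)
    roster = pd.read_csv(
        directory / "roster.csv", dtype=str, keep_default_na=False
    )
    roster["resolvable"] = roster["resolvable"] == "True"
    adt = pd.read_csv(directory / "adt.csv", dtype={"encounter_id": str})
    records = pd.read_csv(
        directory / "records.csv",
        dtype=str,
        keep_default_na=False,
    )
    if len(records):
        records["timestamp"] = pd.to_datetime(records["timestamp"])
        records["system_initiated"] = records["system_initiated"] == "True"
        records["student"] = records["student"] == "True"
        records["truth_burst_id"] = records["truth_burst_id"].astype(np.int64)
    else:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        records = _finalize_records(records)
    truth = GroundTruth.from_dict(json.loads((directory / "truth.json").read_text()))
    return SyntheticStudy(
        encounters=encounters,
        roster=roster,
        adt=adt,
        records=records,
        truth=truth,
        config=None,
    )
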