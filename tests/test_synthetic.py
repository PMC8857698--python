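"""Synthetic cohort generator: determinism, planted structure, round-trips."""

import math

import numpy as np
import pandas as pd
import pytest

import carenet as cn
from carenet.shifts import DAY_START_MINUTE, SHIFT_MINUTES

from helpers import make_records  # noqa: F401  (shared test utilities)


def small_config(**overrides):
    base = dict(n_encounters=40, seed=11)
    base.update(overrides)
    return cn.GeneratorConfig(**base)


def global_shift_of(ts: pd.Timestamp) -> int:
    # independent re-computation of the 07:00/19:00 rotation index
    minutes = (ts - pd.Timestamp("2000-01-01")).total_seconds() / 60.0
    return math.floor((minutes - DAY_START_MINUTE) / SHIFT_MINUTES)


class TestGenerateCohort:
    def test_day_fraction_one_puts_all_arrivals_in_day_window(self):
        study = cn.generate_cohort(small_config(n_encounters=100, day_fraction=1.0))
        hours = study.encounters["arrival_clock"].dt.hour
        assert ((hours >= 7) & (hours < 19)).all()
        assert len(study.encounters) == 100

    def test_day_arrival_count_within_binomial_bounds(self):
        study = cn.generate_cohort(cn.GeneratorConfig(n_encounters=413, day_fraction=0.659, seed=7))
        hours = study.encounters["arrival_clock"].dt.hour
        n_day = int(((hours >= 7) & (hours < 19)).sum())
        sd = math.sqrt(413 * 0.659 * 0.341)
        assert abs(n_day - 272) <= 3 * sd

    def test_same_config_same_seed_is_reproducible(self, tmp_path):
        cfg = small_config()
        a = cn.generate_study(cfg)
        b = cn.generate_study(small_config())
        assert a.equals(b)
        pa = cn.write_raw_dataset(a, tmp_path / "a")
        pb = cn.write_raw_dataset(b, tmp_path / "b")
        for name in pa:
            assert pa[name].read_bytes() == pb[name].read_bytes()

    def test_roster_covers_every_ground_truth_role(self):
        study = cn.generate_cohort(small_config())
        planted = study.roster[study.roster["kind"] == "planted"]
        labels = {
            cn.make_label(r["true_service"], r["generic_role"]) for _, r in planted.iterrows()
        }
        for table in (study.truth.day, study.truth.night):
            for spec in table.values():
                assert spec.all_roles() <= labels

    @pytest.mark.parametrize(
        "overrides, field",
        [
            (dict(day_fraction=1.5), "day_fraction"),
            (dict(n_encounters=0), "n_encounters"),
            (dict(within_burst_gap_minutes=(5.0, 200.0)), "within_burst_gap_minutes"),
            (dict(locations=("FLOOR",)), "locations"),
        ],
    )
    def test_invalid_config_names_offending_field(self, overrides, field):
        with pytest.raises(cn.ConfigurationError, match=field):
            cn.GeneratorConfig(**overrides).validate()


class TestGenerateActivityRecords:
    def test_ground_truth_role_missing_from_roster_raises(self):
        cfg = small_config()
        study = cn.generate_cohort(cfg)
        study.roster = study.roster[study.roster["true_service"] != "GPS"]
        with pytest.raises(cn.GenerationError, match="GPS"):
            cn.generate_activity_records(study, cfg)

    def test_within_burst_gaps_stay_below_break_scale(self, default_study):
        rec = default_study.records.sort_values(["truth_burst_id", "timestamp"])
        for _, grp in rec.groupby("truth_burst_id"):
            gaps = grp["timestamp"].diff().dt.total_seconds().dropna() / 60.0
            assert (gaps < 30).all()

    def test_burst_gap_separation_is_recoverable(self, default_study):
        # within one (encounter, shift), consecutive events either belong to
        # the same burst (short gap) or different bursts (gap above the
        # between-burst support minimum)
        rec = default_study.records.copy()
        rec["gshift"] = [global_shift_of(t) for t in rec["timestamp"]]
        rec = rec.sort_values(["encounter_id", "timestamp"])
        w_hi = 10.0 + 1.0  # within-burst gap support + extra-record jitter
        b_lo = 150.0
        for _, grp in rec.groupby(["encounter_id", "gshift"]):
            gaps = grp["timestamp"].diff().dt.total_seconds().to_numpy()[1:] / 60.0
            same_burst = grp["truth_burst_id"].to_numpy()[1:] == grp["truth_burst_id"].to_numpy()[:-1]
            assert (gaps[same_burst] <= w_hi).all()
            assert (gaps[~same_burst] >= b_lo - w_hi).all()

    def test_planted_cooccurrence_counts(self, default_study):
        """Default night config: within-community pairs share >= 15 shifts,
        cross-community non-hub pairs share <= 3 (direct count on records)."""
        study = default_study
        rec = study.records[study.records["hcp_id"].str.startswith("H")].copy()
        roster = study.roster.set_index("hcp_id")
        rec["role"] = [
            cn.make_label(roster.loc[h, "true_service"], roster.loc[h, "generic_role"])
            for h in rec["hcp_id"]
        ]
        rec["gshift"] = [global_shift_of(t) for t in rec["timestamp"]]
        rec["loc"] = rec.groupby("truth_burst_id")["care_location"].transform(
            lambda s: next((x for x in s if x), "")
        )
        # location of note/flowsheet bursts: recover from any order in the burst;
        # bursts may be all-notes, so fall back to the ADT position
        adt = {
            enc: list(zip(g["location"], g["start_minute"], g["end_minute"]))
            for enc, g in study.adt.groupby("encounter_id")
        }
        arrivals = study.encounters.set_index("encounter_id")["arrival_clock"]

        def locate(row):
            if row["loc"]:
                return row["loc"]
            t = (row["timestamp"] - arrivals[row["encounter_id"]]).total_seconds() / 60.0
            for loc, s, e in adt[row["encounter_id"]]:
                if s <= t < e:
                    return loc
            return adt[row["encounter_id"]][-1][0]

        rec["loc"] = [locate(r) for _, r in rec.iterrows()]
        rec["shift_type"] = np.where(rec["gshift"] % 2 == 0, "day", "night")

        for loc in ("ED", "FLOOR"):
            sub = rec[(rec["loc"] == loc) & (rec["shift_type"] == "night")]
            pair_shifts: dict[tuple, set] = {}
            for (_enc, _g, _b), grp in sub.groupby(["encounter_id", "gshift", "truth_burst_id"]):
                roles = sorted(set(grp["role"]))
                for i in range(len(roles)):
                    for j in range(i + 1, len(roles)):
                        pair_shifts.setdefault((roles[i], roles[j]), set()).add((_enc, _g))
            counts = {p: len(s) for p, s in pair_shifts.items()}
            planted = study.truth.planted_pairs(loc, "night")
            cross = study.truth.cross_pairs(loc, "night")
            for pair in planted:
                assert counts.get(pair, 0) >= 15, (loc, pair, counts.get(pair, 0))
            for pair in cross:
                assert counts.get(pair, 0) <= 3, (loc, pair, counts.get(pair, 0))

    def test_zero_noise_bursts_never_mix_communities(self):
        cfg = small_config(noise_coocc_rate=0.0, n_encounters=60)
        study = cn.generate_study(cfg)
        roster = study.roster.set_index("hcp_id")
        rec = study.records[study.records["hcp_id"].str.startswith("H")].copy()
        rec["role"] = [
            cn.make_label(roster.loc[h, "true_service"], roster.loc[h, "generic_role"])
            for h in rec["hcp_id"]
        ]
        specs = [
            spec
            for table in (study.truth.day, study.truth.night)
            for spec in table.values()
        ]
        for _, grp in rec.groupby("truth_burst_id"):
            roles = set(grp["role"])
            assert any(
                roles <= spec.community_roles(i)
                for spec in specs
                for i in range(len(spec.communities))
            ), roles

    def test_student_system_fraction_within_binomial_bounds(self):
        f = 0.1
        study = cn.generate_study(cn.GeneratorConfig(n_encounters=200, student_system_fraction=f, seed=5))
        n = len(study.records)
        flagged = int((study.records["student"] | study.records["system_initiated"]).sum())
        sd = math.sqrt(n * f * (1 - f))
        assert abs(flagged - f * n) <= 3 * sd

    def test_unresolved_fraction_within_binomial_bounds(self):
        f = 0.08
        study = cn.generate_study(cn.GeneratorConfig(n_encounters=200, unresolved_role_fraction=f, seed=5))
        n = len(study.records)
        unresolved = int(study.records["hcp_id"].str.startswith("U").sum())
        sd = math.sqrt(n * f * (1 - f))
        assert abs(unresolved - f * n) <= 3 * sd


class TestRawDatasetIO:
    def test_round_trip_preserves_study(self, tmp_path):
        study = cn.generate_study(small_config())
        cn.write_raw_dataset(study, tmp_path)
        back = cn.read_raw_dataset(tmp_path)
        pd.testing.assert_frame_equal(study.encounters, back.encounters)
        pd.testing.assert_frame_equal(study.roster, back.roster)
        pd.testing.assert_frame_equal(study.adt, back.adt)
        pd.testing.assert_frame_equal(study.records, back.records)
        assert study.truth.to_dict() == back.truth.to_dict()

    def test_empty_record_list_writes_headers_only(self, tmp_path):
        study = cn.generate_cohort(small_config())
        paths = cn.write_raw_dataset(study, tmp_path)
        text = paths["records"].read_text().strip().splitlines()
        assert len(text) == 1  # header only
        back = cn.read_raw_dataset(tmp_path)
        assert len(back.records) == 0

    def test_truth_serialization_identity(self, tmp_path):
        study = cn.generate_cohort(small_config())
        cn.write_raw_dataset(study, tmp_path)
        back = cn.read_raw_dataset(tmp_path)
        assert back.truth.to_dict() == study.truth.to_dict()
        assert back.truth.planted_pairs("ED", "night") == study.truth.planted_pairs("ED", "night")


class TestAdtInvariants:
    def test_adt_intervals_contiguous_and_start_at_zero(self, default_study):
        for _, grp in default_study.adt.groupby("encounter_id"):
            grp = grp.sort_values("start_minute")
            assert grp["start_minute"].iloc[0] == 0
            assert (grp["end_minute"].to_numpy()[:-1] == grp["start_minute"].to_numpy()[1:]).all()

    def test_every_record_references_a_known_encounter(self, default_study):
        known = set(default_study.encounters["encounter_id"])
        assert set(default_study.records["encounter_id"]) <= known
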