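"""Event-log preparation: normalization, exclusions, inference, resolution."""

import numpy as np
import pandas as pd
import pytest

import carenet as cn
from carenet.eventlog import (
    REASON_INCOMPLETE,
    REASON_OFF_BASE,
    REASON_STUDENT,
    REASON_SYSTEM,
    REASON_UNRESOLVED,
)

from helpers import make_encounters, make_records


ARRIVAL = pd.Timestamp("2017-03-01 08:00:00")


@pytest.fixture
def encounters():
    return make_encounters([{"encounter_id": "E0001", "arrival_clock": ARRIVAL}])


class TestNormalizeTimestamps:
    def test_normalization_arithmetic(self, encounters):
        records = make_records(
            [
                {"timestamp": ARRIVAL},
                {"timestamp": ARRIVAL + pd.Timedelta(seconds=90)},
                {"timestamp": ARRIVAL + pd.Timedelta(minutes=30)},
                {"timestamp": ARRIVAL + pd.Timedelta(minutes=40)},
            ]
        )
        out = cn.normalize_timestamps(records, encounters)
        assert out["t_norm"].tolist() == [0.0, 1.5, 30.0, 40.0]
        # translation invariance: differences do not depend on the arrival clock
        assert out["t_norm"].iloc[3] - out["t_norm"].iloc[2] == 10.0

    def test_pre_arrival_records_are_excluded_not_clamped(self, encounters):
        records = make_records(
            [
                {"timestamp": ARRIVAL - pd.Timedelta(minutes=5)},
                {"timestamp": ARRIVAL + pd.Timedelta(minutes=5)},
            ]
        )
        kept, excluded = cn.normalize_timestamps(records, encounters, return_excluded=True)
        assert len(kept) == 1 and kept["t_norm"].iloc[0] == 5.0
        assert len(excluded) == 1 and (excluded["t_norm"] < 0).all()

    def test_unknown_encounter_raises(self, encounters):
        records = make_records([{"encounter_id": "E9999"}])
        with pytest.raises(cn.DataError, match="E9999"):
            cn.normalize_timestamps(records, encounters)


class TestApplyExclusions:
    def test_reason_codes_and_partition(self, encounters):
        records = make_records(
            [
                {"student": True},
                {"system_initiated": True},
                {"hcp_id": ""},
                {},
            ]
        )
        records = cn.normalize_timestamps(records, encounters)
        kept, excluded = cn.apply_exclusions(records)
        assert len(kept) + len(excluded) == len(records)
        assert len(kept) == 1
        assert sorted(excluded["exclusion_reason"]) == sorted(
            [REASON_STUDENT, REASON_SYSTEM, REASON_INCOMPLETE]
        )


class TestInferLocation:
    TIMELINE = [("ED", 0.0, 120.0), ("PICU", 120.0, 3000.0)]

    @pytest.mark.parametrize(
        "t, expected",
        [(60.0, "ED"), (0.0, "ED"), (120.0, "PICU"), (5000.0, "PICU")],
    )
    def test_half_open_lookup_with_clamp(self, t, expected):
        assert cn.infer_location(t, self.TIMELINE) == expected

    def test_negative_time_is_a_contract_violation(self):
        with pytest.raises(cn.ContractError):
            cn.infer_location(-1.0, self.TIMELINE)

    def test_inference_applies_to_notes_and_flowsheets_only(self, encounters):
        adt = pd.DataFrame(
            [
                {"encounter_id": "E0001", "location": "ED", "start_minute": 0.0, "end_minute": 100.0},
                {"encounter_id": "E0001", "location": "FLOOR", "start_minute": 100.0, "end_minute": 500.0},
            ]
        )
        records = make_records(
            [
                {"activity_type": "note", "timestamp": ARRIVAL + pd.Timedelta(minutes=150)},
                {"activity_type": "flowsheet", "timestamp": ARRIVAL + pd.Timedelta(minutes=50)},
                {
                    "activity_type": "medication_order",
                    "care_location": "PICU",
                    "timestamp": ARRIVAL + pd.Timedelta(minutes=150),
                },
            ]
        )
        records = cn.normalize_timestamps(records, encounters)
        out = cn.infer_locations(records, adt)
        assert out["care_location"].tolist() == ["FLOOR", "ED", "PICU"]


class TestResolveFunctionalRoles:
    def test_resident_takes_cosigning_attending_service_per_encounter(self, encounters):
        records = make_records(
            [
                {
                    "hcp_id": "R1",
                    "generic_role": "resident",
                    "activity_type": "note",
                    "cosigner_service": "Neurosurg",
                },
                {"hcp_id": "R1", "generic_role": "resident", "activity_type": "medication_order",
                 "care_location": "ED", "timestamp": ARRIVAL + pd.Timedelta(minutes=10)},
            ]
        )
        records = cn.normalize_timestamps(records, encounters)
        resolved, excluded = cn.resolve_functional_roles(records)
        assert len(excluded) == 0
        assert set(resolved["functional_role"]) == {"Neurosurg_R"}

    def test_nurse_takes_modal_location_everywhere(self):
        encounters = make_encounters([{"encounter_id": "E0001"}])
        rows = [
            {"hcp_id": "N1", "generic_role": "nurse", "activity_type": "flowsheet",
             "care_location": "ED", "timestamp": ARRIVAL + pd.Timedelta(minutes=i)}
            for i in range(10)
        ] + [
            {"hcp_id": "N1", "generic_role": "nurse", "activity_type": "flowsheet",
             "care_location": "PICU", "timestamp": ARRIVAL + pd.Timedelta(minutes=100 + i)}
            for i in range(2)
        ]
        records = cn.normalize_timestamps(make_records(rows), encounters)
        resolved, excluded = cn.resolve_functional_roles(records)
        assert set(resolved["functional_role"]) == {"ED_RN"}
        # the off-base-unit flowsheets are excluded, not relabeled
        assert len(excluded) == 2
        assert set(excluded["exclusion_reason"]) == {REASON_OFF_BASE}

    def test_hcp_without_service_evidence_is_fully_excluded(self, encounters):
        records = make_records(
            [
                {"hcp_id": "X1", "generic_role": "resident", "activity_type": "medication_order",
                 "care_location": "ED"},
                {"hcp_id": "X1", "generic_role": "resident", "activity_type": "medication_order",
                 "care_location": "ED", "timestamp": ARRIVAL + pd.Timedelta(minutes=9)},
            ]
        )
        records = cn.normalize_timestamps(records, encounters)
        resolved, excluded = cn.resolve_functional_roles(records)
        assert len(resolved) == 0
        assert set(excluded["exclusion_reason"]) == {REASON_UNRESOLVED}

    def test_attending_service_from_notes_with_roster_fallback(self, encounters):
        records = make_records(
            [
                {"hcp_id": "A1", "generic_role": "attending", "activity_type": "note", "service": "Ortho"},
                {"hcp_id": "A2", "generic_role": "attending", "activity_type": "medication_order",
                 "care_location": "ED"},
            ]
        )
        roster = pd.DataFrame(
            [{"hcp_id": "A2", "generic_role": "attending", "true_service": "GPS", "resolvable": True}]
        )
        records = cn.normalize_timestamps(records, encounters)
        resolved, excluded = cn.resolve_functional_roles(records, roster)
        assert len(excluded) == 0
        assert sorted(resolved["functional_role"]) == ["GPS_AT", "Ortho_AT"]

    def test_resolution_is_order_independent(self, encounters):
        rows = []
        for i in range(6):
            rows.append(
                {"record_id": f"R{i}", "hcp_id": "N1", "generic_role": "nurse",
                 "activity_type": "flowsheet", "care_location": "ED" if i % 2 else "PICU",
                 "timestamp": ARRIVAL + pd.Timedelta(minutes=i)}
            )
        rows.append({"record_id": "R9", "hcp_id": "N1", "generic_role": "nurse",
                     "activity_type": "flowsheet", "care_location": "ED",
                     "timestamp": ARRIVAL + pd.Timedelta(minutes=30)})
        records = cn.normalize_timestamps(make_records(rows), encounters)
        shuffled = records.sample(frac=1.0, random_state=4).reset_index(drop=True)
        r1, _ = cn.resolve_functional_roles(records)
        r2, _ = cn.resolve_functional_roles(shuffled)
        m1 = dict(zip(r1["record_id"], r1["functional_role"]))
        m2 = dict(zip(r2["record_id"], r2["functional_role"]))
        assert m1 == m2


class TestBuildMasterLog:
    def test_cosigned_note_fans_out_into_two_same_time_events(self, encounters):
        records = make_records(
            [
                {"hcp_id": "R1", "generic_role": "resident", "activity_type": "note",
                 "cosigner_service": "GPS", "care_location": "ED"},
            ]
        )
        records = cn.normalize_timestamps(records, encounters)
        resolved, _ = cn.resolve_functional_roles(records)
        events = cn.build_master_log(resolved, encounters)
        assert len(events) == 2
        assert events["t_norm"].nunique() == 1
        assert sorted(events["functional_role"]) == ["GPS_AT", "GPS_R"]

    @pytest.mark.parametrize(
        "arrival, t_norm, shift_number, shift_type",
        [
            ("2017-03-01 08:00", 0.0, 0, "day"),
            ("2017-03-01 08:00", 700.0, 1, "night"),  # clock 19:40
            ("2017-03-01 18:50", 15.0, 1, "night"),  # clock 19:05
            ("2017-03-01 20:00", 0.0, 0, "night"),
            ("2017-03-01 20:00", 660.0, 1, "day"),  # next morning 07:00
        ],
    )
    def test_shift_labels_follow_the_wall_clock(self, arrival, t_norm, shift_number, shift_type):
        arrival = pd.Timestamp(arrival)
        encounters = make_encounters([{"arrival_clock": arrival}])
        records = make_records(
            [{"activity_type": "note", "service": "ED",
              "timestamp": arrival + pd.Timedelta(minutes=t_norm)}]
        )
        records = cn.normalize_timestamps(records, encounters)
        resolved, _ = cn.resolve_functional_roles(records)
        events = cn.build_master_log(resolved, encounters)
        assert events["shift_number"].iloc[0] == shift_number
        assert events["shift_type"].iloc[0] == shift_type

    def test_shift_types_invariant_under_24h_arrival_translation(self, encounters):
        records = make_records(
            [
                {"activity_type": "note", "service": "ED",
                 "timestamp": ARRIVAL + pd.Timedelta(minutes=m)}
                for m in (0, 300, 700, 1500)
            ]
        )
        later = make_encounters(
            [{"encounter_id": "E0001", "arrival_clock": ARRIVAL + pd.Timedelta(hours=24)}]
        )
        records_later = records.copy()
        records_later["timestamp"] = records_later["timestamp"] + pd.Timedelta(hours=24)

        ev1 = cn.build_master_log(
            cn.resolve_functional_roles(cn.normalize_timestamps(records, encounters))[0],
            encounters,
        )
        ev2 = cn.build_master_log(
            cn.resolve_functional_roles(cn.normalize_timestamps(records_later, later))[0],
            later,
        )
        assert ev1["shift_type"].tolist() == ev2["shift_type"].tolist()
        assert ev1["shift_number"].tolist() == ev2["shift_number"].tolist()


class TestPrepareMasterLogOnSyntheticData:
    def test_partition_property(self, default_study, default_master):
        master, exclusions = default_master
        # fan-out adds events, so compare against kept record IDs instead
        kept_ids = set(master["record_id"])
        excl_ids = set(exclusions["record_id"])
        all_ids = set(default_study.records["record_id"])
        assert kept_ids | excl_ids == all_ids
        assert not kept_ids & excl_ids

    def test_unresolved_fraction_matches_generator_setting(self, default_study, default_master):
        _, exclusions = default_master
        f = default_study.config.unresolved_role_fraction
        n = len(default_study.records)
        n_unresolved = int((exclusions["exclusion_reason"] == REASON_UNRESOLVED).sum())
        sd = np.sqrt(n * f * (1 - f))
        assert abs(n_unresolved - f * n) <= 3 * sd

    def test_master_log_sorted_within_encounters(self, default_master):
        master, _ = default_master
        for _, grp in master.groupby("encounter_id", sort=False):
            assert (grp["t_norm"].diff().dropna() >= 0).all()
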