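"""Functional-role vocabulary.

A *functional role* is the unit of collaboration in the networks: a clinical
service prefixed to a generic role, e.g. ``Neurosurg_R`` for a neurosurgery
resident or ``ED_RN`` for an emergency-department nurse.  The abbreviation
table mirrors standard usage at pediatric trauma centers.
"""

from __future__ import annotations

from dataclasses import dataclass

#: generic clinical role -> abbreviation used in functional-role labels
ROLE_ABBREVIATIONS: dict[str, str] = {
    "attending": "AT",
    "fellow": "F",
    "resident": "R",
    "nurse": "RN",
    "nurse_practitioner": "NP",
    "physician_assistant": "PA",
    "nurse_technician": "RN_Tech",
    "radiology_technician": "Rad_Tech",
    "social_worker": "SW",
    "child_life_specialist": "CLS",
    "case_manager": "CM",
    "dietitian": "DT",
    "occupational_therapist": "OT",
    "physical_therapist": "PT",
    "pharmacist": "Pharm",
    "home_care_coordinator": "HCC",
    "imaging_data_coordinator": "IDC",
}

_ABBREV_TO_ROLE = {v: k for k, v in ROLE_ABBREVIATIONS.items()}

#: care locations analysed by the pipeline
LOCATIONS = ("ED", "FLOOR", "PICU")

#: service bound to each care location, used when a role is resolved by the
#: modal location of its activities (nurses, unit NPs, allied HCPs)
LOCATION_SERVICE = {"ED": "ED", "FLOOR": "Floor", "PICU": "PICU"}

#: generic roles whose service is fixed (taken from roster / note metadata)
FIXED_SERVICE_ROLES = frozenset({"attending", "fellow", "physician_assistant"})

#: generic roles resolved per encounter from the cosigning attending's service
ENCOUNTER_RESOLVED_ROLES = frozenset({"resident", "radiology_technician"})

ACTIVITY_TYPES = (
    "note",
    "procedure_order",
    "medication_order",
    "flowsheet",
    "medication_admin",
)


@dataclass(frozen=True)
class FunctionalRole:
    """A service-prefixed generic role."""

    service: str
    generic_role: str

    def __post_init__(self):
        if "_" in self.service:
            raise ValueError(f"service may not contain '_': {self.service!r}")
        if self.generic_role not in ROLE_ABBREVIATIONS:
            raise ValueError(f"unknown generic role: {self.generic_role!r}")

    @property
    def label(self) -> str:
        return f"{self.service}_{ROLE_ABBREVIATIONS[self.generic_role]}"


def make_label(service: str, generic_role: str) -> str:
    """Functional-role label ``<service>_<abbrev>``."""
    return FunctionalRole(service, generic_role).label


def parse_label(label: str) -> FunctionalRole:
    """Invert :func:`make_label`; services may not contain underscores."""
    service, _, abbrev = label.partition("_")
    if abbrev not in _ABBREV_TO_ROLE:
        raise ValueError(f"cannot parse functional-role label {label!r}")
    return FunctionalRole(service, _ABBREV_TO_ROLE[abbrev])
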