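"""Shared record types for long-format clinical-event extracts.

The EMR stores everything that happens around a blood transfusion as
independent *clinical events*: one row for the transfusion initiation, one
for its completion, one per vital-sign reading, one for the consent
acknowledgement, and so on.  Every stage of this package passes these rows
around as :class:`ClinicalEventRecord` instances.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import datetime


class Role(enum.StrEnum):
    """What a clinical event means for transfusion reconstruction."""

    INITIATE = "INITIATE"
    COMPLETE = "COMPLETE"
    CONSENT = "CONSENT"
    COMPATIBILITY = "COMPATIBILITY"
    OBSERVATION = "OBSERVATION"
    OTHER = "OTHER"


class Category(enum.StrEnum):
    """The four vital-sign categories that must each be documented."""

    PULSE = "PULSE"
    RESP_RATE = "RESP_RATE"
    TEMPERATURE = "TEMPERATURE"
    BLOOD_PRESSURE = "BLOOD_PRESSURE"


#: Status values for the post-transfusion observation measure.
POST_PASS = "PASS"
POST_FAIL = "FAIL"
POST_NOT_ASSESSABLE = "NOT_ASSESSABLE"

#: Status values for hourly subintervals.
HOURLY_REQUIRED_PASS = "REQUIRED_PASS"
HOURLY_REQUIRED_FAIL = "REQUIRED_FAIL"
HOURLY_NOT_REQUIRED = "NOT_REQUIRED"


@dataclass(frozen=True, slots=True)
class ClinicalEventRecord:
    """One long-format EMR row.

    ``row_id`` identifies the physical row and changes when a record is
    corrected; ``event_key`` identifies the logical event and is stable
    across versions, with ``updt_cnt`` ordering the versions (higher is
    more recent).  ``batch_id`` records which extract file delivered the
    row and is *not* part of the record's logical payload.
    """

    row_id: str
    event_key: str
    patient_id: str
    encounter_id: str
    result_name: str
    result_value: str
    event_dt_tm: datetime
    updt_cnt: int
    facility: str
    ward: str
    medical_service: str
    batch_id: str = ""

    def payload(self) -> tuple:
        """Logical content used for version-conflict detection.

        Excludes ``row_id`` (new per physical row) and ``batch_id``
        (delivery metadata), so redelivery of the same row in a different
        batch is recognised as a duplicate, not a conflict.
        """
        return (
            self.event_key,
            self.patient_id,
            self.encounter_id,
            self.result_name,
            self.result_value,
            self.event_dt_tm,
            self.updt_cnt,
            self.facility,
            self.ward,
            self.medical_service,
        )

    def same_payload(self, other: "ClinicalEventRecord") -> bool:
        return self.payload() == other.payload()
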