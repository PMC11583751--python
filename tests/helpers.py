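"""Shared factories for constructing event rows and episodes in tests."""

from __future__ import annotations

from datetime import datetime, timedelta

from hemovigil import ClinicalEventRecord

BASE = datetime(2021, 12, 1, 0, 0)

_counter = [0]


def at(hour: int, minute: int = 0, day: int = 1) -> datetime:
    return datetime(2021, 12, day, hour, minute)


def rec(
    result_name: str,
    when: datetime,
    *,
    key: str | None = None,
    value: str = "x",
    encounter: str = "E1",
    patient: str = "P1",
    updt_cnt: int = 1,
    facility: str = "Hospital A",
    ward: str = "Ward A1",
    service: str = "General Medicine",
    row_id: str | None = None,
    batch_id: str = "b0",
) -> ClinicalEventRecord:
    _counter[0] += 1
    key = key or f"K{_counter[0]:05d}"
    return ClinicalEventRecord(
        row_id=row_id or f"{key}.v{updt_cnt}",
        event_key=key,
        patient_id=patient,
        encounter_id=encounter,
        result_name=result_name,
        result_value=value,
        event_dt_tm=when,
        updt_cnt=updt_cnt,
        facility=facility,
        ward=ward,
        medical_service=service,
        batch_id=batch_id,
    )


def obs_rows(start: datetime, offsets_min: dict[str, int], **kw) -> list[ClinicalEventRecord]:
    """One observation row per category at start+offset (same offset allowed)."""
    forms = {
        "PULSE": "Heart Rate",
        "RESP_RATE": "Respiratory Rate",
        "TEMPERATURE": "Temperature Oral",
        "BLOOD_PRESSURE": "Systolic Blood Pressure",
    }
    return [
        rec(forms[cat], start + timedelta(minutes=off), **kw)
        for cat, off in offsets_min.items()
    ]


def full_interval(start: datetime, offset_min: int, **kw) -> list[ClinicalEventRecord]:
    """All four categories at the same minute."""
    return obs_rows(start, {c: offset_min for c in
                            ("PULSE", "RESP_RATE", "TEMPERATURE", "BLOOD_PRESSURE")}, **kw)
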