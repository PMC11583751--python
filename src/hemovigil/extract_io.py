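"""Reading, writing and canonicalizing raw EMR extract files.

An extract is a UTF-8 comma-separated file with a header row and one row
per clinical event.  The canonical column set is::

    ROW_ID, EVENT_KEY, PATIENT_ID, ENCNTR_ID, RESULT_NAME, RESULT_VAL,
    EVENT_DT_TM, UPDT_CNT, FACILITY, WARD, MED_SERVICE

Source systems with different column names are adapted through a
:class:`ColumnMap`, which also carries the controlled vocabulary that maps
``RESULT_NAME`` strings to event roles and vital-sign categories.  Rows
missing a value in a critical column are routed to a reject list with a
reason rather than raised, mirroring the defensive filtering a source
extraction query would apply.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import yaml

from .records import Category, ClinicalEventRecord, Role

CANONICAL_COLUMNS = (
    "ROW_ID",
    "EVENT_KEY",
    "PATIENT_ID",
    "ENCNTR_ID",
    "RESULT_NAME",
    "RESULT_VAL",
    "EVENT_DT_TM",
    "UPDT_CNT",
    "FACILITY",
    "WARD",
    "MED_SERVICE",
)

DEFAULT_CRITICAL = ("EVENT_KEY", "ENCNTR_ID", "RESULT_NAME", "EVENT_DT_TM", "UPDT_CNT")

# Timestamps outside this range are treated as data-entry garbage.
SANE_MIN = datetime(1990, 1, 1)
SANE_MAX = datetime(2100, 1, 1)

# Controlled vocabulary: extractable source forms for each vital-sign
# category, and the event-type strings for the non-observation roles.
# The names are this package's own; any site vocabulary can be supplied
# through a ColumnMap config file.
DEFAULT_VITAL_SIGN_FORMS: dict[str, Category] = {
    "Peripheral Pulse Rate": Category.PULSE,
    "Heart Rate": Category.PULSE,
    "Respiratory Rate": Category.RESP_RATE,
    "Temperature Axillary": Category.TEMPERATURE,
    "Temperature Oesophageal": Category.TEMPERATURE,
    "Temperature Oral": Category.TEMPERATURE,
    "Temperature Tympanic": Category.TEMPERATURE,
    "Systolic Blood Pressure": Category.BLOOD_PRESSURE,
    "Diastolic Blood Pressure": Category.BLOOD_PRESSURE,
}

DEFAULT_EVENT_ROLES: dict[str, Role] = {
    "Transfusion Initiate": Role.INITIATE,
    "Transfusion Complete": Role.COMPLETE,
    "Blood Product Consent": Role.CONSENT,
    "Blood Compatibility Check": Role.COMPATIBILITY,
}


class ExtractFormatError(ValueError):
    """The extract file cannot be interpreted at all (e.g. missing header)."""


@dataclass(frozen=True)
class RejectedRow:
    raw: dict
    reason: str
    line_no: int


@dataclass
class ColumnMap:
    """Source-to-canonical column mapping plus the result-name vocabulary.

    ``columns`` maps source column names to canonical names; by default the
    identity mapping on the canonical set.  ``critical`` lists canonical
    columns that must be non-blank for a row to survive.
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in CANONICAL_COLUMNS}
    )
    critical: tuple[str, ...] = DEFAULT_CRITICAL
    vital_sign_forms: dict[str, Category] = field(
        default_factory=lambda: dict(DEFAULT_VITAL_SIGN_FORMS)
    )
    event_roles: dict[str, Role] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_ROLES)
    )

    def __post_init__(self) -> None:
        canonical = list(self.columns.values())
        if sorted(canonical) != sorted(set(canonical)):
            raise ExtractFormatError("column map assigns a canonical field twice")
        missing = set(CANONICAL_COLUMNS) - set(canonical)
        if missing:
            raise ExtractFormatError(f"column map missing canonical fields: {sorted(missing)}")
        overlap = set(self.vital_sign_forms) & set(self.event_roles)
        if overlap:
            raise ExtractFormatError(
                f"result names mapped to both a role and a category: {sorted(overlap)}"
            )
        self.vital_sign_forms = {k: Category(v) for k, v in self.vital_sign_forms.items()}
        self.event_roles = {k: Role(v) for k, v in self.event_roles.items()}

    # -- role / category classification ---------------------------------

    def role_of(self, result_name: str) -> Role:
        if result_name in self.event_roles:
            return self.event_roles[result_name]
        if result_name in self.vital_sign_forms:
            return Role.OBSERVATION
        return Role.OTHER

    def category_of(self, result_name: str) -> Category | None:
        return self.vital_sign_forms.get(result_name)

    def forms_for(self, category: Category) -> list[str]:
        return sorted(n for n, c in self.vital_sign_forms.items() if c == category)

    def role_names(self, role: Role) -> list[str]:
        return sorted(n for n, r in self.event_roles.items() if r == role)

    # -- config file round trip ------------------------------------------

    def to_dict(self) -> dict:
        return {
            "columns": dict(self.columns),
            "critical": list(self.critical),
            "vital_sign_forms": {k: str(v) for k, v in self.vital_sign_forms.items()},
            "event_roles": {k: str(v) for k, v in self.event_roles.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColumnMap":
        kwargs: dict = {}
        if "columns" in d:
            kwargs["columns"] = dict(d["columns"])
        if "critical" in d:
            kwargs["critical"] = tuple(d["critical"])
        if "vital_sign_forms" in d:
            kwargs["vital_sign_forms"] = {
                k: Category(v) for k, v in d["vital_sign_forms"].items()
            }
        if "event_roles" in d:
            kwargs["event_roles"] = {k: Role(v) for k, v in d["event_roles"].items()}
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ColumnMap":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def classify(record: ClinicalEventRecord, column_map: ColumnMap) -> tuple[Role, Category | None]:
    """Classify a record into a role and, for observations, a category.

    Total and deterministic: unknown result names map to ``OTHER`` and are
    retained by callers, never silently dropped.
    """
    role = column_map.role_of(record.result_name)
    category = column_map.category_of(record.result_name) if role is Role.OBSERVATION else None
    return role, category


def parse_timestamp(text: str) -> datetime:
    """Parse an ISO-8601 timestamp at minute precision; raise ValueError."""
    dt = datetime.fromisoformat(text.strip())
    if dt.tzinfo is not None:
        raise ValueError("timezone-aware timestamps are not supported")
    dt = dt.replace(second=0, microsecond=0)
    if not (SANE_MIN <= dt <= SANE_MAX):
        raise ValueError(f"timestamp {text!r} outside sane range")
    return dt


def format_timestamp(dt: datetime) -> str:
    return dt.strftime("%Y-%m-%dT%H:%M")


def read_extract(
    path: str | Path,
    column_map: ColumnMap | None = None,
    batch_id: str | None = None,
) -> tuple[list[ClinicalEventRecord], list[RejectedRow]]:
    """Read one extract file into canonical records plus rejects.

    Rows missing any critical value go to the reject list with reason
    ``"missing-critical"``; unparseable or out-of-range timestamps reject
    with ``"bad-timestamp"``, malformed version counters with
    ``"bad-version"``.  Ordering of surviving rows is preserved.
    """
    cmap = column_map or ColumnMap()
    path = Path(path)
    bid = batch_id if batch_id is not None else path.stem
    source_for = {canon: src for src, canon in cmap.columns.items()}

    records: list[ClinicalEventRecord] = []
    rejects: list[RejectedRow] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ExtractFormatError(f"{path}: empty file, no header row")
        header = set(reader.fieldnames)
        missing_cols = [source_for[c] for c in CANONICAL_COLUMNS if source_for[c] not in header]
        if missing_cols:
            raise ExtractFormatError(f"{path}: missing columns {missing_cols}")

        for line_no, raw in enumerate(reader, start=2):
            get = lambda canon: (raw.get(source_for[canon]) or "").strip()
            if any(get(c) == "" for c in cmap.critical):
                rejects.append(RejectedRow(raw, "missing-critical", line_no))
                continue
            try:
                dt = parse_timestamp(get("EVENT_DT_TM"))
            except ValueError:
                rejects.append(RejectedRow(raw, "bad-timestamp", line_no))
                continue
            try:
                updt_cnt = int(get("UPDT_CNT"))
                if updt_cnt < 0:
                    raise ValueError
            except ValueError:
                rejects.append(RejectedRow(raw, "bad-version", line_no))
                continue
            row_id = get("ROW_ID") or f"{bid}:{line_no}"
            records.append(
                ClinicalEventRecord(
                    row_id=row_id,
                    event_key=get("EVENT_KEY"),
                    patient_id=get("PATIENT_ID"),
                    encounter_id=get("ENCNTR_ID"),
                    result_name=get("RESULT_NAME"),
                    result_value=get("RESULT_VAL"),
                    event_dt_tm=dt,
                    updt_cnt=updt_cnt,
                    facility=get("FACILITY"),
                    ward=get("WARD"),
                    medical_service=get("MED_SERVICE"),
                    batch_id=bid,
                )
            )
    return records, rejects


def write_extract(records, path: str | Path) -> Path:
    """Write canonical records as an extract CSV (canonical column names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.row_id,
                    r.event_key,
                    r.patient_id,
                    r.encounter_id,
                    r.result_name,
                    r.result_value,
                    format_timestamp(r.event_dt_tm),
                    r.updt_cnt,
                    r.facility,
                    r.ward,
                    r.medical_service,
                ]
            )
    return path
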