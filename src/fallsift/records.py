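"""Core EHR record types and plain-file IO.

The pipeline works on four kinds of structured input: free-text clinical
notes, surgery records (one row per surgical admission), ICD-coded fall
diagnoses, and official fall-report timestamps.  Notes travel as JSON-Lines
(one object per line); everything tabular travels as CSV with ISO-8601 dates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd


class NoteType(str, Enum):
    PROGRESS = "progress"
    NURSING = "nursing"
    FALL_REPORT = "fall_report"
    OTHER = "other"


class Label(str, Enum):
    """Binary classification outcome; ``ABSTAIN`` marks an unparseable response."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    ABSTAIN = "abstain"


class IntegrityError(ValueError):
    """Cross-record consistency violation (id mismatch, span out of bounds)."""


@dataclass(frozen=True)
class ClinicalNote:
    """One timestamped free-text document tied to a patient/encounter.

    ``text`` may be empty; ``timestamp`` is always present.
    """

    note_id: str
    patient_id: str
    encounter_id: str
    timestamp: datetime
    note_type: NoteType = NoteType.OTHER
    text: str = ""

    def __post_init__(self) -> None:
        if self.timestamp is None:
            raise ValueError(f"note {self.note_id!r}: timestamp is required")


@dataclass(frozen=True)
class SurgeryRecord:
    """A surgical admission: the anchor for the postsurgical observation window."""

    patient_id: str
    surgery_date: date
    age_at_surgery: int
    admission_date: Optional[date]
    discharge_date: Optional[date]
    death_date: Optional[date] = None
    record_id: str = ""

    def __post_init__(self) -> None:
        if self.age_at_surgery < 0:
            raise ValueError(f"age_at_surgery must be >= 0, got {self.age_at_surgery}")
        if (
            self.admission_date is not None
            and self.discharge_date is not None
            and not (self.admission_date <= self.surgery_date <= self.discharge_date)
        ):
            raise ValueError(
                f"record {self.record_id!r}: require admission <= surgery <= discharge"
            )


class CodeSystem(str, Enum):
    ICD9CM = "ICD9CM"
    ICD10CM = "ICD10CM"


@dataclass(frozen=True)
class IcdFallRecord:
    patient_id: str
    code: str
    code_system: CodeSystem
    date: date

    def __post_init__(self) -> None:
        if not self.code:
            raise ValueError("ICD code must be non-empty")


@dataclass(frozen=True)
class FallReport:
    """Timestamp of an official (templated) fall-report note for a patient."""

    patient_id: str
    timestamp: datetime


# ---------------------------------------------------------------------------
# JSON-Lines / CSV round-trips


def _parse_datetime(value: str) -> datetime:
    return datetime.fromisoformat(value)


def _parse_date(value) -> Optional[date]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return date.fromisoformat(str(value))


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for note in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": note.note_id,
                        "patient_id": note.patient_id,
                        "encounter_id": note.encounter_id,
                        "timestamp": note.timestamp.isoformat(),
                        "note_type": note.note_type.value,
                        "text": note.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    notes: list[ClinicalNote] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            if obj["note_id"] in seen:
                raise IntegrityError(f"duplicate note_id {obj['note_id']!r}")
            seen.add(obj["note_id"])
            notes.append(
                ClinicalNote(
                    note_id=obj["note_id"],
                    patient_id=obj["patient_id"],
                    encounter_id=obj.get("encounter_id", ""),
                    timestamp=_parse_datetime(obj["timestamp"]),
                    note_type=NoteType(obj.get("note_type", "other")),
                    text=obj.get("text", ""),
                )
            )
    return notes


def write_surgeries_csv(records: Iterable[SurgeryRecord], path: str | Path) -> None:
    rows = [
        {
            "patient_id": r.patient_id,
            "record_id": r.record_id,
            "surgery_date": r.surgery_date.isoformat(),
            "age_at_surgery": r.age_at_surgery,
            "admission_date": r.admission_date.isoformat() if r.admission_date else "",
            "discharge_date": r.discharge_date.isoformat() if r.discharge_date else "",
            "death_date": r.death_date.isoformat() if r.death_date else "",
        }
        for r in records
    ]
    pd.DataFrame(
        rows,
        columns=[
            "patient_id",
            "record_id",
            "surgery_date",
            "age_at_surgery",
            "admission_date",
            "discharge_date",
            "death_date",
        ],
    ).to_csv(path, index=False)


def read_surgeries_csv(path: str | Path) -> list[SurgeryRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    records = []
    for _, row in df.iterrows():
        records.append(
            SurgeryRecord(
                patient_id=row["patient_id"],
                record_id=row.get("record_id", ""),
                surgery_date=date.fromisoformat(row["surgery_date"]),
                age_at_surgery=int(row["age_at_surgery"]),
                admission_date=_parse_date(row["admission_date"]),
                discharge_date=_parse_date(row["discharge_date"]),
                death_date=_parse_date(row["death_date"]),
            )
        )
    return records


def write_icd_csv(records: Iterable[IcdFallRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "code": r.code,
                "code_system": r.code_system.value,
                "date": r.date.isoformat(),
            }
            for r in records
        ],
        columns=["patient_id", "code", "code_system", "date"],
    ).to_csv(path, index=False)


def read_icd_csv(path: str | Path) -> list[IcdFallRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        IcdFallRecord(
            patient_id=row["patient_id"],
            code=row["code"],
            code_system=CodeSystem(row["code_system"]),
            date=date.fromisoformat(row["date"]),
        )
        for _, row in df.iterrows()
    ]


def write_fall_reports_csv(reports: Iterable[FallReport], path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": r.patient_id, "timestamp": r.timestamp.isoformat()} for r in reports],
        columns=["patient_id", "timestamp"],
    ).to_csv(path, index=False)


def read_fall_reports_csv(path: str | Path) -> list[FallReport]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        FallReport(patient_id=row["patient_id"], timestamp=_parse_datetime(row["timestamp"]))
        for _, row in df.iterrows()
    ]
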