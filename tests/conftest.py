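from datetime import date, datetime

import pytest
from hypothesis import HealthCheck, settings

from fallsift.records import ClinicalNote, NoteType, SurgeryRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_note(
    text: str,
    note_id: str = "n1",
    patient_id: str = "p1",
    ts: str = "2020-01-05T10:00:00",
    note_type: NoteType = NoteType.PROGRESS,
) -> ClinicalNote:
    return ClinicalNote(
        note_id=note_id,
        patient_id=patient_id,
        encounter_id="e1",
        timestamp=datetime.fromisoformat(ts),
        note_type=note_type,
        text=text,
    )


def make_surgery(
    patient_id: str = "p1",
    surgery: str = "2020-01-01",
    age: int = 65,
    stay_days: int = 10,
    admission: str | None = None,
    death: str | None = None,
    record_id: str = "s1",
    missing_discharge: bool = False,
) -> SurgeryRecord:
    from datetime import timedelta

    sdate = date.fromisoformat(surgery)
    adm = date.fromisoformat(admission) if admission else sdate
    return SurgeryRecord(
        patient_id=patient_id,
        record_id=record_id,
        surgery_date=sdate,
        age_at_surgery=age,
        admission_date=adm,
        discharge_date=None if missing_discharge else adm + timedelta(days=stay_days),
        death_date=date.fromisoformat(death) if death else None,
    )


@pytest.fixture
def note_factory():
    return make_note


@pytest.fixture
def surgery_factory():
    return make_surgery
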