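"""Synthetic EHR-like corpus with known ground truth.

Real postsurgical notes cannot leave a hospital firewall, so every pipeline
stage here is exercised on a generated corpus: patients with surgical
admissions (a small fraction deliberately violating the inclusion criteria),
timestamped inpatient notes drawn from five template families matching the
annotation schema (fall events, historical falls, fall-risk language,
miscellaneous uses of "fall/fell", and notes with no fall content), official
fall-report notes covering a configurable fraction of true fall events, and
patient-level ICD fall coding with configurable sensitivity/specificity.

Template families are paraphrase sets with randomized slots (staff, place,
time expressions) so string identity cannot stand in for understanding; a
hard-confounder family (historical and figurative falls) is always present
because historical mentions are the dominant false-positive mode for this
task.  All randomness flows through one ``numpy`` generator keyed by the
config seed, in a fixed draw order, so a fixed seed reproduces the corpus
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import Category, GoldAnnotation, write_annotations_csv
from .records import (
    ClinicalNote,
    CodeSystem,
    FallReport,
    IcdFallRecord,
    IntegrityError,
    Label,
    NoteType,
    SurgeryRecord,
    write_fall_reports_csv,
    write_icd_csv,
    write_notes_jsonl,
    write_surgeries_csv,
)

# --------------------------------------------------------------------------
# Template families.  Slots in {braces} are filled from the pools below.

FALL_EVENT_TEMPLATES = (
    "Patient was found by {staff} quickly moving toward the {place} and then "
    "fallen on the floor by {pron} bed on {pron} bottom.",
    "Patient fell {when} while ambulating to the {place} and was assisted back to bed.",
    "{staff_cap} reported that the patient slipped and fell near the {place} {when}.",
    "Patient found down in the {place} {when}; assessed for injury after the fall.",
    "While getting up without assistance the patient fell, striking {pron} {site}.",
)

HISTORY_TEMPLATES = (
    "Patient with history of dementia had an episode of fall last year and "
    "ended up with {injury}.",
    "Patient also reported frequent falls at home prior to admission, one "
    "recently while {pron} spouse was assisting.",
    "His history, in brief, his pain started after a fall two years ago.",
    "History of falls noted in outside records; prior fall caused {injury}.",
)

FALL_RISK_TEMPLATES = (
    "Patient assessed as high fall risk; recommended assistive devices for balance.",
    "Morse fall risk score elevated {when}; continue close monitoring.",
    "Education provided regarding fall risk and the importance of calling for help.",
    "Fall precautions in place; bed alarm on and call light within reach.",
)

OTHER_MENTION_TEMPLATES = (
    "May need to transfuse if platelets fall < 50.",
    "Ate a quiche, but then fell full after 5 bites and stopped.",
    "Has upcoming trip to Niagara Falls planned with family.",
    "Blood pressure continued to fall overnight; fluids given.",
)

NO_FALL_TEMPLATES = (
    "Patient resting comfortably and denies pain.",
    "Dressing changed; incision clean, dry, and intact.",
    "Tolerating diet and voiding without difficulty.",
    "Ambulating with physical therapy twice daily.",
    "Afebrile; vital signs within normal limits.",
)

FALL_REPORT_TEMPLATE = (
    "FALL REPORT: Patient sustained a fall {when}; incident documented and "
    "provider notified per protocol."
)

_SLOTS = {
    "staff": ("nursing assistant", "the night nurse", "physical therapy staff"),
    "staff_cap": ("Nursing assistant", "The night nurse", "Physical therapy staff"),
    "place": ("restroom", "bathroom", "hallway", "bedside commode"),
    "when": ("this morning", "overnight", "today", "earlier this evening"),
    "pron": ("his", "her"),
    "site": ("left hip", "right shoulder", "forehead"),
    "injury": ("left hip fracture", "wrist fracture", "a scalp laceration"),
}

_TEMPLATES: dict[Category, tuple[str, ...]] = {
    Category.FALL_EVENT: FALL_EVENT_TEMPLATES,
    Category.HISTORY_OF_FALLS: HISTORY_TEMPLATES,
    Category.FALL_RISK: FALL_RISK_TEMPLATES,
    Category.OTHER_MENTION: OTHER_MENTION_TEMPLATES,
    Category.NO_FALL: NO_FALL_TEMPLATES,
}

#: Category mix of the generated notes.  Chosen to mirror the composition of
#: the internal gold set (43.3% fall events, 56.7% negatives) with the
#: negative mass concentrated on historical mentions, the dominant confounder.
DEFAULT_CATEGORY_MIX: dict[Category, float] = {
    Category.FALL_EVENT: 0.433,
    Category.HISTORY_OF_FALLS: 0.250,
    Category.FALL_RISK: 0.100,
    Category.OTHER_MENTION: 0.117,
    Category.NO_FALL: 0.100,
}


class ConfigError(ValueError):
    pass


@dataclass
class CorpusConfig:
    """Knobs of the generator; defaults define the standard study conditions."""

    n_patients: int = 400
    start_date: date = date(2012, 1, 1)
    end_date: date = date(2022, 12, 31)
    notes_per_patient: float = 3.0  # mean, Poisson with minimum 1
    category_mix: Mapping[Category, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    icd_sensitivity: float = 0.77
    icd_specificity: float = 0.95
    report_coverage: float = 0.60
    ineligible_fraction: float = 0.08  # patients violating an inclusion rule
    second_surgery_rate: float = 0.05
    stray_note_rate: float = 0.15  # extra out-of-window note per patient
    seed: int = 0

    def __post_init__(self) -> None:
        mix = {Category(k): float(v) for k, v in self.category_mix.items()}
        if set(mix) != set(Category):
            raise ConfigError(f"category_mix must cover all categories, got {sorted(mix)}")
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ConfigError(f"category proportions must sum to 1, got {sum(mix.values())}")
        for name in ("icd_sensitivity", "icd_specificity", "report_coverage",
                     "ineligible_fraction", "second_surgery_rate", "stray_note_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be >= 0")
        self.category_mix = mix


@dataclass
class Corpus:
    """Everything the pipeline consumes, plus the hidden ground truth."""

    config: CorpusConfig
    surgeries: list[SurgeryRecord]
    notes: list[ClinicalNote]
    icd_records: list[IcdFallRecord]
    fall_reports: list[FallReport]
    annotations: list[GoldAnnotation]

    @property
    def category_by_note(self) -> dict[str, Category]:
        return {a.note_id: a.category for a in self.annotations}

    @property
    def truth_by_note(self) -> dict[str, bool]:
        """Binary ground truth: does the note document a fall event?"""
        return {a.note_id: a.category is Category.FALL_EVENT for a in self.annotations}

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "notes": outdir / "notes.jsonl",
            "surgeries": outdir / "surgeries.csv",
            "icd": outdir / "icd_fall_codes.csv",
            "fall_reports": outdir / "fall_reports.csv",
            "annotations": outdir / "gold_annotations.csv",
        }
        write_notes_jsonl(self.notes, paths["notes"])
        write_surgeries_csv(self.surgeries, paths["surgeries"])
        write_icd_csv(self.icd_records, paths["icd"])
        write_fall_reports_csv(self.fall_reports, paths["fall_reports"])
        write_annotations_csv(self.annotations, paths["annotations"])
        return {k: str(v) for k, v in paths.items()}


def _fill(template: str, rng: np.random.Generator) -> str:
    out = template
    for slot, pool in _SLOTS.items():
        token = "{" + slot + "}"
        if token in out:
            out = out.replace(token, pool[int(rng.integers(len(pool)))])
    return out


def _note_text(category: Category, rng: np.random.Generator) -> str:
    """Filler sentence, one or two category sentences, filler sentence."""
    pool = _TEMPLATES[category]
    body = [_fill(pool[int(rng.integers(len(pool)))], rng)]
    if category is Category.FALL_EVENT and rng.random() < 0.2:
        body.append(_fill(pool[int(rng.integers(len(pool)))], rng))
    fillers = NO_FALL_TEMPLATES
    lead = fillers[int(rng.integers(len(fillers)))]
    tail = fillers[int(rng.integers(len(fillers)))]
    return " ".join([lead, *body, tail])


_NOTE_TYPES = (NoteType.PROGRESS, NoteType.NURSING, NoteType.OTHER)


def generate_corpus(config: CorpusConfig) -> Corpus:
    """Generate the full synthetic corpus for a config; fixed seed, fixed bytes."""
    rng = np.random.default_rng(config.seed)
    span_days = max((config.end_date - config.start_date).days - 130, 1)
    surgeries: list[SurgeryRecord] = []
    notes: list[ClinicalNote] = []
    annotations: list[GoldAnnotation] = []
    fall_reports: list[FallReport] = []
    icd_records: list[IcdFallRecord] = []
    categories = list(Category)
    probs = np.array([config.category_mix[c] for c in categories])

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        encounter = f"E{i:05d}"
        violation = None
        if rng.random() < config.ineligible_fraction:
            violation = ("age", "stay", "death")[int(rng.integers(3))]
        age = int(rng.integers(45, 50)) if violation == "age" else int(rng.integers(50, 95))
        admission = config.start_date + timedelta(days=int(rng.integers(span_days)))
        surgery = admission + timedelta(days=int(rng.integers(0, 4)))
        stay_after = int(rng.integers(95, 111)) if violation == "stay" else int(rng.integers(5, 31))
        discharge = surgery + timedelta(days=stay_after)
        death = surgery + timedelta(days=int(rng.integers(3, 31))) if violation == "death" else None
        surgeries.append(
            SurgeryRecord(
                patient_id=pid,
                record_id=f"S{i:05d}a",
                surgery_date=surgery,
                age_at_surgery=age,
                admission_date=admission,
                discharge_date=discharge,
                death_date=death,
            )
        )
        if rng.random() < config.second_surgery_rate and stay_after > 6:
            surgeries.append(
                SurgeryRecord(
                    patient_id=pid,
                    record_id=f"S{i:05d}b",
                    surgery_date=surgery + timedelta(days=int(rng.integers(3, stay_after))),
                    age_at_surgery=age,
                    admission_date=admission,
                    discharge_date=discharge,
                    death_date=death,
                )
            )

        n_notes = 1 + int(rng.poisson(max(config.notes_per_patient - 1.0, 0.0)))
        for j in range(n_notes):
            note_id = f"N{i:05d}x{j:02d}"
            day = int(rng.integers(1, stay_after + 1))
            ts = datetime.combine(surgery + timedelta(days=day),
                                  time(int(rng.integers(6, 22)), int(rng.integers(0, 60))))
            category = categories[int(rng.choice(len(categories), p=probs))]
            note = ClinicalNote(
                note_id=note_id,
                patient_id=pid,
                encounter_id=encounter,
                timestamp=ts,
                note_type=_NOTE_TYPES[int(rng.integers(len(_NOTE_TYPES)))],
                text=_note_text(category, rng),
            )
            notes.append(note)
            annotations.append(GoldAnnotation(note_id, category, "synthetic_truth"))
            if category is Category.FALL_EVENT and rng.random() < config.report_coverage:
                report_ts = min(
                    ts + timedelta(hours=int(rng.integers(1, 7))),
                    datetime.combine(discharge, time(23, 0)),
                )
                report_id = f"{note_id}R"
                fall_reports.append(FallReport(patient_id=pid, timestamp=report_ts))
                notes.append(
                    ClinicalNote(
                        note_id=report_id,
                        patient_id=pid,
                        encounter_id=encounter,
                        timestamp=report_ts,
                        note_type=NoteType.FALL_REPORT,
                        text=_fill(FALL_REPORT_TEMPLATE, rng),
                    )
                )
                annotations.append(
                    GoldAnnotation(report_id, Category.FALL_EVENT, "synthetic_truth")
                )
        if rng.random() < config.stray_note_rate:
            stray_id = f"N{i:05d}pre"
            notes.append(
                ClinicalNote(
                    note_id=stray_id,
                    patient_id=pid,
                    encounter_id=encounter,
                    timestamp=datetime.combine(admission, time(9, 0)),
                    note_type=NoteType.OTHER,
                    text=_note_text(Category.NO_FALL, rng),
                )
            )
            annotations.append(GoldAnnotation(stray_id, Category.NO_FALL, "synthetic_truth"))

    # Patient-level ICD fall coding, imperfectly linked to true fall events.
    note_patient = {n.note_id: n.patient_id for n in notes}
    fallers = {
        note_patient[a.note_id]
        for a in annotations
        if a.category is Category.FALL_EVENT
    }
    code_pool = (
        ("W19.XXXA", CodeSystem.ICD10CM),
        ("W18.30XA", CodeSystem.ICD10CM),
        ("E888.9", CodeSystem.ICD9CM),
    )
    for rec in surgeries:
        if rec.record_id.endswith("b"):
            continue
        is_faller = rec.patient_id in fallers
        p_code = config.icd_sensitivity if is_faller else 1.0 - config.icd_specificity
        if rng.random() < p_code:
            code, system = code_pool[int(rng.integers(len(code_pool)))]
            icd_records.append(
                IcdFallRecord(
                    patient_id=rec.patient_id,
                    code=code,
                    code_system=system,
                    date=rec.surgery_date + timedelta(days=int(rng.integers(1, 10))),
                )
            )

    return Corpus(
        config=config,
        surgeries=surgeries,
        notes=notes,
        icd_records=icd_records,
        fall_reports=fall_reports,
        annotations=annotations,
    )


def end_to_end_truth_table(
    corpus: Corpus,
    flagged_note_ids: set[str],
    predictions: Mapping[str, Label],
    selected_note_ids: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-note join of ground truth, regex flag, and prediction.

    ``predictions`` holds parsed labels for the notes that reached the
    classifier; unflagged notes are implicitly negative.  Rows are limited to
    ``selected_note_ids`` when given (the postsurgical selection).  A
    prediction for an unknown note id is an integrity error.
    """
    categories = corpus.category_by_note
    known = set(categories)
    unknown = set(predictions) - known
    if unknown:
        raise IntegrityError(f"predictions reference unknown notes: {sorted(unknown)}")
    rows = []
    for note in corpus.notes:
        if selected_note_ids is not None and note.note_id not in selected_note_ids:
            continue
        category = categories[note.note_id]
        truth = category is Category.FALL_EVENT
        parsed = predictions.get(note.note_id)
        predicted = parsed is Label.POSITIVE
        rows.append(
            {
                "note_id": note.note_id,
                "patient_id": note.patient_id,
                "category": category.value,
                "true_label": "positive" if truth else "negative",
                "regex_flagged": note.note_id in flagged_note_ids,
                "classified": parsed is not None,
                "predicted_label": "positive" if predicted else "negative",
                "correct": truth == predicted,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "note_id", "patient_id", "category", "true_label",
            "regex_flagged", "classified", "predicted_label", "correct",
        ],
    )
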