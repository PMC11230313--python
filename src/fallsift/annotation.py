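"""Gold-standard annotation schema and inter-annotator agreement.

Notes are annotated with one of five categories.  Only ``fall_event`` (an
actual patient fall during the index stay) is positive for the detection
task; history of falls, fall-risk language, other uses of the word "fall",
and notes with no fall content are all negative.  This binary grouping is a
partition of the five-way schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from sklearn.metrics import cohen_kappa_score

from .records import Label


class Category(str, Enum):
    FALL_EVENT = "fall_event"
    HISTORY_OF_FALLS = "history_of_falls"
    FALL_RISK = "fall_risk"
    OTHER_MENTION = "other_mention"
    NO_FALL = "no_fall"


class SchemaError(ValueError):
    """Annotation outside the closed category set, or mismatched note sets."""


@dataclass(frozen=True)
class GoldAnnotation:
    note_id: str
    category: Category
    annotator_id: str
    guideline_version: str = "1.0"

    def __post_init__(self) -> None:
        if not isinstance(self.category, Category):
            raise SchemaError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class BinaryLabel:
    note_id: str
    label: Label

    def __post_init__(self) -> None:
        if self.label not in (Label.POSITIVE, Label.NEGATIVE):
            raise ValueError("binary label must be positive or negative")


def to_binary(annotation: GoldAnnotation) -> BinaryLabel:
    """Collapse the five-way category into the fall-event / no-fall-event task."""
    label = Label.POSITIVE if annotation.category is Category.FALL_EVENT else Label.NEGATIVE
    return BinaryLabel(note_id=annotation.note_id, label=label)


def _aligned(
    ann_a: Sequence[GoldAnnotation], ann_b: Sequence[GoldAnnotation]
) -> tuple[list[str], list[str]]:
    map_a = {a.note_id: a.category.value for a in ann_a}
    map_b = {b.note_id: b.category.value for b in ann_b}
    if len(map_a) != len(ann_a) or len(map_b) != len(ann_b):
        raise SchemaError("one category per (note, annotator): duplicate note_id found")
    if set(map_a) != set(map_b):
        diff = sorted(set(map_a) ^ set(map_b))
        raise SchemaError(f"annotators cover different notes; symmetric difference: {diff}")
    ids = sorted(map_a)
    return [map_a[i] for i in ids], [map_b[i] for i in ids]


def cohen_kappa(
    ann_a: Sequence[GoldAnnotation],
    ann_b: Sequence[GoldAnnotation],
    binary: bool = False,
) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Computed over the five-way categories by default; ``binary=True`` first
    collapses to the fall-event / no-fall-event grouping.  Returns 1.0 for
    identical annotations (including the degenerate single-category case
    where the chance correction is 0/0).
    """
    labels_a, labels_b = _aligned(ann_a, ann_b)
    if binary:
        collapse = lambda c: "positive" if c == Category.FALL_EVENT.value else "negative"
        labels_a = [collapse(c) for c in labels_a]
        labels_b = [collapse(c) for c in labels_b]
    if labels_a == labels_b:
        return 1.0
    return float(cohen_kappa_score(labels_a, labels_b))


def disagreement_report(
    ann_a: Sequence[GoldAnnotation], ann_b: Sequence[GoldAnnotation]
) -> dict:
    """Agreement summary plus disagreeing notes listed by category pair."""
    labels_a, labels_b = _aligned(ann_a, ann_b)
    ids = sorted({a.note_id for a in ann_a})
    pairs: dict[str, list[str]] = {}
    for note_id, ca, cb in zip(ids, labels_a, labels_b):
        if ca != cb:
            pairs.setdefault(f"{ca}|{cb}", []).append(note_id)
    return {
        "n_notes": len(ids),
        "kappa_categories": cohen_kappa(ann_a, ann_b),
        "kappa_binary": cohen_kappa(ann_a, ann_b, binary=True),
        "disagreements_by_category_pair": pairs,
    }


def write_annotations_csv(annotations: Iterable[GoldAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "note_id": a.note_id,
                "annotator_id": a.annotator_id,
                "category": a.category.value,
                "guideline_version": a.guideline_version,
            }
            for a in annotations
        ],
        columns=["note_id", "annotator_id", "category", "guideline_version"],
    ).to_csv(path, index=False)


def read_annotations_csv(path: str | Path) -> list[GoldAnnotation]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        GoldAnnotation(
            note_id=row["note_id"],
            annotator_id=row["annotator_id"],
            category=Category(row["category"]),
            guideline_version=row.get("guideline_version", "1.0"),
        )
        for _, row in df.iterrows()
    ]


def write_agreement_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
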