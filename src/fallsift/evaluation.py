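"""Binary-classifier evaluation: PPV, recall, specificity, AUROC, kappa inputs.

For a classifier that emits only binary outputs the ROC curve has a single
interior operating point, so its exact AUROC reduces to

    AUROC = (sensitivity + specificity) / 2,

i.e. balanced accuracy.  :func:`implied_auroc` inverts a published
(precision, recall) pair under a known class balance back to that quantity,
allowing non-integer tp/fp because printed precision/recall are rounded.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Optional, Sequence

from .annotation import Category, GoldAnnotation, to_binary
from .records import Label


class EvaluationError(ValueError):
    """Undefined metric (e.g. no gold positives) or inconsistent inputs."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """Cell counts; reals are allowed to support implied reconstructions."""

    tp: float
    fp: float
    fn: float
    tn: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise EvaluationError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> float:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class EvalReport:
    precision: float
    recall: float
    specificity: float
    auroc: float
    matrix: ConfusionMatrix
    abstain_count: int = 0
    fp_breakdown: Mapping[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "auroc": self.auroc,
            "matrix": {
                "tp": self.matrix.tp,
                "fp": self.matrix.fp,
                "fn": self.matrix.fn,
                "tn": self.matrix.tn,
            },
            "abstain_count": self.abstain_count,
            "fp_breakdown": dict(self.fp_breakdown),
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (table-comparison convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).copy_abs().quantize(q, rounding=ROUND_HALF_UP) * (1 if x >= 0 else -1))


def _as_map(labels: Sequence) -> dict[str, Label]:
    out = {l.note_id: l.label for l in labels}
    if len(out) != len(labels):
        raise EvaluationError("duplicate note_id in label list")
    return out


def confusion_from_labels(preds: Sequence, gold: Sequence) -> ConfusionMatrix:
    p, g = _as_map(preds), _as_map(gold)
    if set(p) != set(g):
        diff = sorted(set(p) ^ set(g))
        raise EvaluationError(f"prediction/gold note sets differ: {diff}")
    tp = fp = fn = tn = 0
    for note_id, gl in g.items():
        pl = p[note_id]
        if gl is Label.POSITIVE:
            tp, fn = (tp + 1, fn) if pl is Label.POSITIVE else (tp, fn + 1)
        else:
            fp, tn = (fp + 1, tn) if pl is Label.POSITIVE else (fp, tn + 1)
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def metrics_from_matrix(m: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(precision, recall, specificity, auroc) from a confusion matrix."""
    if m.tp + m.fn == 0:
        raise EvaluationError("no gold positives: recall undefined")
    if m.fp + m.tn == 0:
        raise EvaluationError("no gold negatives: specificity undefined")
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else float("nan")
    recall = m.tp / (m.tp + m.fn)
    specificity = m.tn / (m.tn + m.fp)
    auroc = (recall + specificity) / 2.0
    return precision, recall, specificity, auroc


def evaluate(
    preds: Sequence,
    gold: Sequence,
    abstain_count: int = 0,
    gold_annotations: Optional[Sequence[GoldAnnotation]] = None,
) -> EvalReport:
    """Score binary predictions against gold binary labels.

    ``preds`` and ``gold`` are :class:`~fallsift.annotation.BinaryLabel`
    sequences over the same note ids.  When five-way ``gold_annotations`` are
    supplied the false positives are additionally broken down by gold
    subcategory.
    """
    matrix = confusion_from_labels(preds, gold)
    precision, recall, specificity, auroc = metrics_from_matrix(matrix)
    breakdown: dict[str, float] = {}
    if gold_annotations is not None:
        counts = fp_breakdown(preds, gold_annotations)
        breakdown = {cat: prop for cat, (_cnt, prop) in counts.items()}
    return EvalReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        auroc=auroc,
        matrix=matrix,
        abstain_count=abstain_count,
        fp_breakdown=breakdown,
    )


def responses_to_binary(parsed: Mapping[str, Label]) -> tuple[list, int]:
    """Map parsed labels to binary predictions; abstain -> negative, counted."""
    from .annotation import BinaryLabel

    out, abstains = [], 0
    for note_id in sorted(parsed):
        label = parsed[note_id]
        if label is Label.ABSTAIN:
            abstains += 1
            label = Label.NEGATIVE
        out.append(BinaryLabel(note_id=note_id, label=label))
    return out, abstains


def implied_auroc(precision: float, recall: float, n_pos: float, n_neg: float) -> float:
    """AUROC implied by a printed (precision, recall) pair and class balance.

    Reconstructs continuous tp/fp counts, derives specificity, and applies
    the two-point identity.  Raises when the inputs are infeasible (the
    implied false positives exceed the number of negatives).
    """
    if not (0 < precision <= 1):
        raise EvaluationError(f"precision must be in (0, 1], got {precision}")
    if not (0 <= recall <= 1):
        raise EvaluationError(f"recall must be in [0, 1], got {recall}")
    if n_pos <= 0 or n_neg <= 0:
        raise EvaluationError("class counts must be positive")
    tp = recall * n_pos
    fp = tp * (1.0 - precision) / precision
    if fp > n_neg * (1 + 1e-12):
        raise EvaluationError(
            f"infeasible inputs: implied fp={fp:.2f} exceeds n_neg={n_neg}"
        )
    specificity = (n_neg - fp) / n_neg
    return (recall + specificity) / 2.0


def fp_breakdown(
    preds: Sequence, gold_annotations: Sequence[GoldAnnotation]
) -> dict[str, tuple[int, float]]:
    """Group false positives by five-way gold subcategory.

    Returns ``{category: (count, proportion of all false positives)}``; empty
    when there are no false positives.
    """
    ann_by_note = {a.note_id: a for a in gold_annotations}
    p = _as_map(preds)
    fp_notes = []
    missing = []
    for note_id, pl in p.items():
        if pl is not Label.POSITIVE:
            continue
        ann = ann_by_note.get(note_id)
        if ann is None:
            missing.append(note_id)
        elif to_binary(ann).label is Label.NEGATIVE:
            fp_notes.append(ann)
    if missing:
        raise EvaluationError(
            f"positive predictions without gold annotations: {sorted(missing)}"
        )
    total = len(fp_notes)
    if total == 0:
        return {}
    counts: dict[str, int] = {}
    for ann in fp_notes:
        counts[ann.category.value] = counts.get(ann.category.value, 0) + 1
    return {cat: (cnt, cnt / total) for cat, cnt in sorted(counts.items())}


# ---------------------------------------------------------------------------
# Published operating points (model, prompting mode, cohort) with the class
# balances of the two gold sets: internal 600 notes (340 negative), external
# 200 notes (120 positive).  Inputs for the implied-AUROC reconstruction and
# the table-layout report.

@dataclass(frozen=True)
class OperatingPoint:
    cohort: str
    mode: str
    model: str
    precision: float
    recall: float
    auroc_printed: float
    n_pos: int
    n_neg: int


REPORTED_OPERATING_POINTS: tuple[OperatingPoint, ...] = (
    OperatingPoint("internal", "few_shot", "llama3_8b", 0.72, 0.90, 0.82, 260, 340),
    OperatingPoint("internal", "few_shot", "gemma_7b", 0.71, 0.93, 0.82, 260, 340),
    OperatingPoint("internal", "few_shot", "mixtral_8x7b", 0.92, 0.56, 0.76, 260, 340),
    OperatingPoint("internal", "zero_shot", "llama3_8b", 0.78, 0.70, 0.77, 260, 340),
    OperatingPoint("internal", "zero_shot", "gemma_7b", 0.71, 0.87, 0.79, 260, 340),
    OperatingPoint("internal", "zero_shot", "mixtral_8x7b", 0.81, 0.67, 0.78, 260, 340),
    OperatingPoint("external", "few_shot", "llama3_8b", 0.98, 0.70, 0.84, 120, 80),
    OperatingPoint("external", "few_shot", "gemma_7b", 0.62, 0.83, 0.54, 120, 80),
    OperatingPoint("external", "few_shot", "mixtral_8x7b", 0.99, 0.57, 0.78, 120, 80),
    OperatingPoint("external", "zero_shot", "llama3_8b", 0.88, 0.99, 0.90, 120, 80),
    OperatingPoint("external", "zero_shot", "gemma_7b", 0.94, 0.84, 0.88, 120, 80),
    OperatingPoint("external", "zero_shot", "mixtral_8x7b", 0.93, 0.94, 0.92, 120, 80),
)


def reconstruct_reported_auroc() -> list[dict]:
    """Implied AUROC for every published operating point, vs the printed value."""
    rows = []
    for op in REPORTED_OPERATING_POINTS:
        implied = implied_auroc(op.precision, op.recall, op.n_pos, op.n_neg)
        rows.append(
            {
                "cohort": op.cohort,
                "mode": op.mode,
                "model": op.model,
                "precision": op.precision,
                "recall": op.recall,
                "auroc_printed": op.auroc_printed,
                "auroc_implied": implied,
                "auroc_implied_2dp": round_half_away(implied, 2),
                "matches_printed": math.isclose(
                    round_half_away(implied, 2), op.auroc_printed, abs_tol=1e-9
                ),
            }
        )
    return rows
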