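"""Cohort inclusion rules and postsurgical note selection.

Inclusion criteria for a surgical admission:

* age at surgery >= 50 years,
* inpatient stay (discharge - admission) <= 90 days,
* no death within 30 days after surgery (death on days 0-30 excludes the
  patient; death on day 31 or later does not),
* only the earliest surgery per patient is retained.

All boundaries are deliberate and tested: age 50 is included, a 90-day stay
is included, a death exactly on day 30 excludes.  Cohort rules compare dates
at day resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import timedelta

from .records import ClinicalNote, SurgeryRecord

logger = logging.getLogger(__name__)

MIN_AGE_YEARS = 50
MAX_STAY_DAYS = 90
DEATH_WINDOW_DAYS = 30


@dataclass
class InclusionLog:
    """Why records were dropped, for funnel reporting."""

    n_in: int = 0
    n_out: int = 0
    rejected: dict[str, int] = field(default_factory=dict)

    def count(self, reason: str) -> None:
        self.rejected[reason] = self.rejected.get(reason, 0) + 1


def _eligible(rec: SurgeryRecord, log: InclusionLog) -> bool:
    if rec.admission_date is None or rec.discharge_date is None:
        log.count("missing_admission_or_discharge")
        logger.info("rejected %s/%s: missing admission/discharge date",
                    rec.patient_id, rec.record_id)
        return False
    if rec.age_at_surgery < MIN_AGE_YEARS:
        log.count("age_below_minimum")
        return False
    if (rec.discharge_date - rec.admission_date).days > MAX_STAY_DAYS:
        log.count("stay_over_maximum")
        return False
    if rec.death_date is not None and (
        (rec.death_date - rec.surgery_date).days <= DEATH_WINDOW_DAYS
    ):
        log.count("death_within_30_days")
        return False
    return True


def apply_inclusion(
    surgeries: list[SurgeryRecord], log: InclusionLog | None = None
) -> list[SurgeryRecord]:
    """Filter surgery records by the study's inclusion criteria.

    Returns at most one record per patient (the earliest surgery among the
    patient's eligible records; ties on surgery date broken by lowest
    ``record_id``).  Output is sorted by (patient_id, surgery_date), so the
    operation is deterministic and idempotent.
    """
    log = log if log is not None else InclusionLog()
    log.n_in = len(surgeries)
    eligible = [r for r in surgeries if _eligible(r, log)]
    first: dict[str, SurgeryRecord] = {}
    for rec in sorted(eligible, key=lambda r: (r.patient_id, r.surgery_date, r.record_id)):
        first.setdefault(rec.patient_id, rec)
    out = sorted(first.values(), key=lambda r: (r.patient_id, r.surgery_date))
    log.n_out = len(out)
    return out


def select_postsurgical_notes(
    cohort: list[SurgeryRecord],
    notes: list[ClinicalNote],
    log: InclusionLog | None = None,
) -> list[ClinicalNote]:
    """Keep notes dated strictly after surgery and up to discharge (inclusive).

    The window is half-open at day resolution: a note dated on the surgery
    date itself is excluded, a note dated on the discharge date is included.
    Notes for patients outside the cohort are dropped silently but counted.
    """
    log = log if log is not None else InclusionLog()
    log.n_in = len(notes)
    window = {r.patient_id: (r.surgery_date, r.discharge_date) for r in cohort}
    selected = []
    for note in notes:
        if note.patient_id not in window:
            log.count("patient_not_in_cohort")
            continue
        surgery_date, discharge_date = window[note.patient_id]
        note_day = note.timestamp.date()
        if surgery_date < note_day <= discharge_date:
            selected.append(note)
        else:
            log.count("outside_window")
    selected.sort(key=lambda n: (n.patient_id, n.timestamp, n.note_id))
    log.n_out = len(selected)
    return selected


@dataclass(frozen=True)
class OverlapSummary:
    """Patient-level agreement between note flagging and ICD fall coding."""

    n_cohort: int
    flagged_and_coded: int
    coded_only: int
    flagged_only: int
    neither: int

    @property
    def proportions(self) -> dict[str, float]:
        n = self.n_cohort
        return {
            "flagged_and_coded": self.flagged_and_coded / n,
            "coded_only": self.coded_only / n,
            "flagged_only": self.flagged_only / n,
            "neither": self.neither / n,
        }

    @property
    def flagged_given_coded(self) -> float:
        """P(regex-flagged | ICD-coded); NaN when no patient is coded."""
        n_coded = self.flagged_and_coded + self.coded_only
        return self.flagged_and_coded / n_coded if n_coded else float("nan")


def code_vs_mention_overlap(
    cohort: set[str], flagged: set[str], coded: set[str]
) -> OverlapSummary:
    """Cross-tabulate regex-flagged vs ICD-coded patients over a cohort."""
    if not cohort:
        raise ValueError("empty cohort: no denominator for overlap proportions")
    if not flagged <= cohort or not coded <= cohort:
        raise ValueError("flagged and coded sets must be subsets of the cohort")
    both = len(flagged & coded)
    coded_only = len(coded - flagged)
    flagged_only = len(flagged - coded)
    neither = len(cohort) - both - coded_only - flagged_only
    return OverlapSummary(len(cohort), both, coded_only, flagged_only, neither)
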