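"""Targeted sampling around official fall reports (external-validation triage).

Notes are triaged relative to each patient's official fall-report
timestamps:

* **likely positive** — written within 24 hours *after* a report,
  window ``(t_report, t_report + 24 h]``;
* **possibly positive** — written within 30 days *before* a report,
  window ``[t_report - 30 d, t_report)``;
* **likely negative** — any note from a patient with no report at all.

A note qualifying for both windows (reports close together) lands in likely
positive only.  Notes of reported patients outside both windows belong to no
stratum — likely negative is defined at the patient level — and are counted
in the log.  "One month" is fixed to 30 days; both window sizes are
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import timedelta
from enum import Enum
from typing import Sequence

import numpy as np

from .records import ClinicalNote, FallReport


class StratumName(str, Enum):
    LIKELY_POSITIVE = "likely_positive"
    POSSIBLY_POSITIVE = "possibly_positive"
    LIKELY_NEGATIVE = "likely_negative"


@dataclass(frozen=True)
class SamplingStratum:
    name: StratumName
    note_ids: tuple[str, ...]


class SamplingError(ValueError):
    pass


@dataclass
class StrataResult:
    likely_positive: SamplingStratum
    possibly_positive: SamplingStratum
    likely_negative: SamplingStratum
    unassigned: tuple[str, ...] = ()

    def __iter__(self):
        return iter((self.likely_positive, self.possibly_positive, self.likely_negative))

    def by_name(self, name: StratumName) -> SamplingStratum:
        return {s.name: s for s in self}[name]


def categorize_notes(
    notes: Sequence[ClinicalNote],
    fall_reports: Sequence[FallReport],
    positive_window: timedelta = timedelta(hours=24),
    prior_window: timedelta = timedelta(days=30),
) -> StrataResult:
    """Assign each note to a sampling stratum (or leave it unassigned)."""
    reports_by_patient: dict[str, list] = {}
    for r in fall_reports:
        reports_by_patient.setdefault(r.patient_id, []).append(r.timestamp)
    likely_pos, possibly_pos, likely_neg, unassigned = [], [], [], []
    for note in notes:
        if note.timestamp is None:
            raise SamplingError(f"note {note.note_id!r} has no timestamp")
        timestamps = reports_by_patient.get(note.patient_id)
        if timestamps is None:
            likely_neg.append(note.note_id)
            continue
        in_after = any(t < note.timestamp <= t + positive_window for t in timestamps)
        in_prior = any(t - prior_window <= note.timestamp < t for t in timestamps)
        if in_after:
            likely_pos.append(note.note_id)
        elif in_prior:
            possibly_pos.append(note.note_id)
        else:
            unassigned.append(note.note_id)
    return StrataResult(
        likely_positive=SamplingStratum(StratumName.LIKELY_POSITIVE, tuple(likely_pos)),
        possibly_positive=SamplingStratum(StratumName.POSSIBLY_POSITIVE, tuple(possibly_pos)),
        likely_negative=SamplingStratum(StratumName.LIKELY_NEGATIVE, tuple(likely_neg)),
        unassigned=tuple(unassigned),
    )


def draw_sample(
    strata: StrataResult,
    sizes: dict[StratumName, int] | Sequence[int],
    seed: int,
) -> list[str]:
    """Uniform without-replacement draw from each stratum, reproducibly.

    ``sizes`` may be a dict keyed by stratum name or a 3-sequence in stratum
    order (likely positive, possibly positive, likely negative).  Output
    order is stratum order then draw order.
    """
    if not isinstance(sizes, dict):
        sizes = dict(zip(list(StratumName), sizes))
    rng = np.random.default_rng(seed)
    sample: list[str] = []
    for stratum in strata:
        k = int(sizes.get(stratum.name, 0))
        n = len(stratum.note_ids)
        if k > n:
            raise SamplingError(
                f"stratum {stratum.name.value!r} has {n} notes; cannot draw {k}"
            )
        if k:
            idx = rng.choice(n, size=k, replace=False)
            sample.extend(stratum.note_ids[i] for i in idx)
    return sample
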