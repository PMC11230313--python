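"""Regex fall-mention tagging: the preliminary note filter.

A :class:`TaggerProtocol` is an ordered set of named inclusion patterns
(word-boundary forms of fall/falls/fell/fallen/falling plus "found down")
and named exclusion patterns for preventive-care boilerplate ("fall
precautions", "fall(s) prevention").  A mention survives when its sentence
contains no exclusion-pattern match.  Only precaution boilerplate is
excluded: fall-*risk* language and figurative uses ("platelets fall < 50",
"Niagara Falls") deliberately pass the filter — disambiguating those is the
classifier's job, and the gold annotation schema has categories for them.

Overlapping inclusion matches are resolved leftmost-longest, so the returned
mentions are disjoint in character space and sorted by offset.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chunker import DEFAULT_ABBREVIATIONS, sentence_index_of, split_sentences
from .records import ClinicalNote


class TaggerConfigError(ValueError):
    """Invalid protocol configuration (bad regex, duplicate names, ...)."""


@dataclass(frozen=True)
class PatternDef:
    name: str
    pattern: str


@dataclass(frozen=True)
class FallMention:
    """One regex hit: character span, matched surface form, sentence index."""

    note_id: str
    start: int
    end: int
    surface: str
    sentence_index: int
    pattern_name: str


@dataclass(frozen=True)
class TaggerProtocol:
    """Named inclusion/exclusion patterns plus case handling.

    The protocol is immutable; :meth:`compile` returns a separate compiled
    object and never mutates the definition.
    """

    inclusion_patterns: tuple[PatternDef, ...]
    exclusion_patterns: tuple[PatternDef, ...] = ()
    case_sensitive: bool = False

    def compile(self) -> "CompiledProtocol":
        names = [p.name for p in self.inclusion_patterns + self.exclusion_patterns]
        if len(set(names)) != len(names):
            raise TaggerConfigError(f"duplicate pattern names in {names}")
        if not self.inclusion_patterns:
            raise TaggerConfigError("at least one inclusion pattern is required")
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            inc = [(p.name, re.compile(p.pattern, flags)) for p in self.inclusion_patterns]
            exc = [(p.name, re.compile(p.pattern, flags)) for p in self.exclusion_patterns]
        except re.error as err:
            raise TaggerConfigError(f"invalid pattern {err.pattern!r}: {err}") from err
        return CompiledProtocol(self, inc, exc)

    def with_exclusion(self, name: str, pattern: str) -> "TaggerProtocol":
        return replace(
            self, exclusion_patterns=self.exclusion_patterns + (PatternDef(name, pattern),)
        )


@dataclass(frozen=True)
class CompiledProtocol:
    definition: TaggerProtocol
    inclusion: list[tuple[str, re.Pattern]]
    exclusion: list[tuple[str, re.Pattern]]


#: Default lexicon.  The published pattern set this reconstructs was
#: site-extended and is treated as configuration, not as a fixed constant.
DEFAULT_PROTOCOL = TaggerProtocol(
    inclusion_patterns=(
        PatternDef("fall_forms", r"\b(?:fall|falls|falling|fallen|fell)\b"),
        PatternDef("found_down", r"\bfound down\b"),
    ),
    exclusion_patterns=(
        PatternDef("fall_precautions", r"\bfall\s+precautions?\b"),
        PatternDef("fall_prevention", r"\bfalls?\s+prevention\b"),
    ),
)


def _leftmost_longest(candidates: list[tuple[int, int, str]]) -> list[tuple[int, int, str]]:
    """Greedy disjoint selection: earliest start wins, longest match at a start."""
    chosen: list[tuple[int, int, str]] = []
    last_end = -1
    for start, end, name in sorted(candidates, key=lambda c: (c[0], -c[1])):
        if start >= last_end:
            chosen.append((start, end, name))
            last_end = end
    return chosen


def tag_note(
    note: ClinicalNote,
    protocol: TaggerProtocol | CompiledProtocol = DEFAULT_PROTOCOL,
    abbreviations=DEFAULT_ABBREVIATIONS,
) -> list[FallMention]:
    """Return all surviving fall mentions in a note, sorted by offset.

    A mention is suppressed when any exclusion pattern matches anywhere in
    the sentence containing it (sentence-scoped local context).
    """
    compiled = protocol.compile() if isinstance(protocol, TaggerProtocol) else protocol
    text = note.text
    if not text:
        return []
    candidates: list[tuple[int, int, str]] = []
    for name, pat in compiled.inclusion:
        candidates.extend((m.start(), m.end(), name) for m in pat.finditer(text))
    if not candidates:
        return []
    spans = split_sentences(text, abbreviations)
    excluded_sentences = {
        s.index
        for s in spans
        if any(pat.search(text, s.start, s.end) for _, pat in compiled.exclusion)
    }
    mentions = []
    for start, end, name in _leftmost_longest(candidates):
        idx = sentence_index_of(spans, start)
        if idx in excluded_sentences:
            continue
        mentions.append(
            FallMention(
                note_id=note.note_id,
                start=start,
                end=end,
                surface=text[start:end],
                sentence_index=idx,
                pattern_name=name,
            )
        )
    return mentions


@dataclass
class FilterSummary:
    n_notes_in: int = 0
    n_notes_flagged: int = 0
    n_patients_flagged: int = 0
    flagged_patient_ids: set[str] = field(default_factory=set)

    @property
    def n_notes_unflagged(self) -> int:
        return self.n_notes_in - self.n_notes_flagged


def filter_corpus(
    notes: Sequence[ClinicalNote],
    protocol: TaggerProtocol | CompiledProtocol = DEFAULT_PROTOCOL,
) -> tuple[list[tuple[ClinicalNote, list[FallMention]]], FilterSummary]:
    """Apply the tagger to every note; keep notes with >= 1 mention.

    Output order follows input order, so the result is deterministic for a
    fixed input ordering.
    """
    compiled = protocol.compile() if isinstance(protocol, TaggerProtocol) else protocol
    summary = FilterSummary(n_notes_in=len(notes))
    flagged: list[tuple[ClinicalNote, list[FallMention]]] = []
    for note in notes:
        mentions = tag_note(note, compiled)
        if mentions:
            flagged.append((note, mentions))
            summary.flagged_patient_ids.add(note.patient_id)
    summary.n_notes_flagged = len(flagged)
    summary.n_patients_flagged = len(summary.flagged_patient_ids)
    return flagged, summary


def write_mentions_csv(mentions: Iterable[FallMention], path) -> None:
    import pandas as pd

    pd.DataFrame(
        [
            {
                "note_id": m.note_id,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "pattern_name": m.pattern_name,
                "sentence_index": m.sentence_index,
            }
            for m in mentions
        ],
        columns=["note_id", "start", "end", "surface", "pattern_name", "sentence_index"],
    ).to_csv(path, index=False)
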