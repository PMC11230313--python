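"""Sentence segmentation and ±1-sentence context chunks.

The unit sent to the classifier is a *note chunk*: for every tagged fall
mention in a note, the sentence before, the sentence containing the mention,
and the sentence after are taken; when a note holds several mentions the
windows are unioned (deduplicated, document order) and joined with single
spaces.  Naive concatenation would duplicate sentences whenever windows
overlap and distort the prompt, so the union is used instead.

Segmentation is rule-based: terminal punctuation (``. ! ?``) followed by
whitespace or end-of-text closes a sentence, newlines are hard boundaries,
and a configurable guard list of clinical abbreviations ("Dr.", "q.i.d.",
...) suppresses spurious splits.  This is deterministic and adequate for the
template-like structure of clinical notes; no syntactic parsing is attempted.
"""

from __future__ import annotations

import bisect
import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .records import ClinicalNote
    from .tagger import FallMention

#: Tokens whose trailing period does not end a sentence (lower-case,
#: without the final period).  Single capital letters are deliberately not
#: guarded: initials like "A. B." split, which errs toward shorter sentences.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "st", "jr", "sr",
        "vs", "etc", "approx", "dept", "fig", "al",
        "pt", "pts", "md", "m.d", "r.n", "p.o", "i.v",
        "e.g", "i.e", "q.d", "b.i.d", "t.i.d", "q.i.d", "p.r.n",
    }
)

_TERMINAL = re.compile(r"[.!?]+")
_TRAILING_TOKEN = re.compile(r"([A-Za-z][A-Za-z.]*)$")


@dataclass(frozen=True)
class SentenceSpan:
    """Character extent of one sentence; offsets index into the note text."""

    index: int
    start: int
    end: int


def split_sentences(
    text: str, abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS
) -> list[SentenceSpan]:
    """Segment ``text`` into ordered, non-overlapping sentence spans.

    Spans are trimmed of surrounding whitespace and cover all non-whitespace
    characters; an empty text yields an empty list.
    """
    if not text:
        return []
    cuts = {0, len(text)}
    for m in _TERMINAL.finditer(text):
        end = m.end()
        if end < len(text) and not text[end].isspace():
            continue  # mid-token punctuation, e.g. "3.5" or "x.y"
        if m.group() == ".":
            tok = _TRAILING_TOKEN.search(text, 0, m.start())
            if tok and tok.group(1).lower().rstrip(".") in abbreviations:
                continue
            if tok and tok.group(1).lower() in abbreviations:
                continue
        cuts.add(end)
    for i, ch in enumerate(text):
        if ch == "\n":
            cuts.add(i)
            cuts.add(i + 1)
    ordered = sorted(cuts)
    spans: list[SentenceSpan] = []
    for lo, hi in zip(ordered, ordered[1:]):
        segment = text[lo:hi]
        stripped = segment.strip()
        if not stripped:
            continue
        start = lo + (len(segment) - len(segment.lstrip()))
        end = start + len(stripped)
        spans.append(SentenceSpan(index=len(spans), start=start, end=end))
    return spans


def sentence_index_of(spans: Sequence[SentenceSpan], offset: int) -> int:
    """Index of the sentence containing character ``offset``.

    Offsets falling in inter-sentence whitespace attach to the preceding
    sentence (the nearest span starting at or before the offset).
    """
    if not spans:
        raise ValueError("no sentences")
    starts = [s.start for s in spans]
    i = bisect.bisect_right(starts, offset) - 1
    return max(i, 0)


@dataclass(frozen=True)
class NoteChunk:
    """Concatenated ±1-sentence windows around all mentions in one note."""

    note_id: str
    text: str
    mention_count: int
    source_sentence_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.mention_count < 1:
            raise ValueError("a chunk requires at least one mention")
        if not self.text:
            raise ValueError("chunk text must be non-empty")


def build_note_chunk(
    note: "ClinicalNote",
    mentions: Sequence["FallMention"],
    abbreviations: frozenset[str] | set[str] = DEFAULT_ABBREVIATIONS,
    max_sentences: Optional[int] = None,
) -> NoteChunk:
    """Build the classifier input chunk for one note.

    For each mention in sentence ``i`` the window ``{i-1, i, i+1}`` (clipped
    to document bounds) is selected; windows from all mentions are unioned in
    document order.  ``max_sentences`` optionally caps the chunk (first N
    selected sentences) for backends with hard context limits; off by default.
    """
    from .records import IntegrityError

    if not mentions:
        raise ValueError(f"note {note.note_id!r}: mentions must be non-empty")
    spans = split_sentences(note.text, abbreviations)
    n = len(spans)
    selected: set[int] = set()
    for m in mentions:
        if m.note_id != note.note_id:
            raise IntegrityError(
                f"mention for note {m.note_id!r} passed with note {note.note_id!r}"
            )
        if not (0 <= m.start < m.end <= len(note.text)):
            raise IntegrityError(
                f"mention span ({m.start}, {m.end}) outside note {note.note_id!r}"
            )
        i = sentence_index_of(spans, m.start)
        selected.update(j for j in (i - 1, i, i + 1) if 0 <= j < n)
    indices = sorted(selected)
    if max_sentences is not None:
        indices = indices[:max_sentences]
    text = " ".join(note.text[spans[j].start : spans[j].end] for j in indices)
    return NoteChunk(
        note_id=note.note_id,
        text=text,
        mention_count=len(mentions),
        source_sentence_indices=tuple(indices),
    )
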