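"""Regex fall-mention tagging: lexicon hits, precaution exclusion, oracle equality."""

import re

import numpy as np
import pytest

from fallsift.chunker import split_sentences
from fallsift.tagger import (
    DEFAULT_PROTOCOL,
    PatternDef,
    TaggerConfigError,
    TaggerProtocol,
    filter_corpus,
    tag_note,
)

from .conftest import make_note

# Word pool for random clinical-ish strings: lexicon forms, exclusion-phrase
# parts, and neutral filler, so random draws hit every code path.
WORDS = [
    "fall", "falls", "fell", "fallen", "falling", "found", "down",
    "precaution", "precautions", "prevention", "patient", "the", "bed",
    "platelets", "50", "risk", "Dr.", "again.", "home",
]


def random_text(rng: np.random.Generator, max_words: int = 12) -> str:
    n = int(rng.integers(0, max_words))
    return " ".join(str(rng.choice(WORDS)) for _ in range(n))


def bruteforce_tag(text: str, protocol: TaggerProtocol) -> list[tuple[int, int]]:
    """Independent oracle: anchored match at every character offset."""
    flags = 0 if protocol.case_sensitive else re.IGNORECASE
    candidates = []
    for p in protocol.inclusion_patterns:
        pat = re.compile(p.pattern, flags)
        for pos in range(len(text) + 1):
            m = pat.match(text, pos)
            if m and m.end() > m.start():
                candidates.append((m.start(), m.end()))
    # leftmost-longest greedy selection over disjoint spans
    chosen, last_end = [], -1
    for start, end in sorted(candidates, key=lambda c: (c[0], -c[1])):
        if start >= last_end:
            chosen.append((start, end))
            last_end = end
    # sentence-scoped exclusion, scanning every offset for every pattern
    spans = split_sentences(text)
    excluded = set()
    for s in spans:
        for p in protocol.exclusion_patterns:
            pat = re.compile(p.pattern, flags)
            if any(
                pat.match(text, pos) and pat.match(text, pos).end() <= s.end
                for pos in range(s.start, s.end)
            ):
                excluded.add((s.start, s.end))
    out = []
    for start, end in chosen:
        sentence = next(((s.start, s.end) for s in spans if s.start <= start < s.end), None)
        if sentence not in excluded:
            out.append((start, end))
    return out


class TestTagNote:
    def test_figurative_platelets_fall_is_tagged(self):
        mentions = tag_note(make_note("May need to transfuse if platelets fall < 50."))
        assert [m.surface for m in mentions] == ["fall"]

    def test_empty_text(self):
        assert tag_note(make_note("")) == []

    def test_precaution_sentence_fully_excluded(self):
        text = "Fall precautions: we discussed falls prevention efforts"
        assert tag_note(make_note(text)) == []

    def test_precaution_exclusion_is_sentence_scoped(self):
        text = "Fall precautions in place. Patient later fell near the bed."
        mentions = tag_note(make_note(text))
        assert [m.surface for m in mentions] == ["fell"]
        assert mentions[0].sentence_index == 1

    def test_fallen_on_floor_tagged(self):
        mentions = tag_note(make_note("then fallen on the floor by his bed"))
        assert [m.surface for m in mentions] == ["fallen"]

    def test_surface_matches_span(self):
        note = make_note("Patient fell today. Found down once more.")
        for m in tag_note(note):
            assert note.text[m.start : m.end] == m.surface

    def test_invalid_pattern_names_the_culprit(self):
        bad = TaggerProtocol(inclusion_patterns=(PatternDef("broken", r"fall("),))
        with pytest.raises(TaggerConfigError, match="fall"):
            bad.compile()

    def test_duplicate_pattern_names_rejected(self):
        dup = TaggerProtocol(
            inclusion_patterns=(PatternDef("x", "fall"), PatternDef("x", "fell"))
        )
        with pytest.raises(TaggerConfigError, match="duplicate"):
            dup.compile()


class TestProperties:
    def test_mentions_disjoint_and_sorted(self):
        rng = np.random.default_rng(0)
        for i in range(100):
            mentions = tag_note(make_note(random_text(rng)))
            for a, b in zip(mentions, mentions[1:]):
                assert a.end <= b.start

    def test_case_insensitive_by_default(self):
        rng = np.random.default_rng(1)
        for i in range(100):
            text = random_text(rng)
            spans = [(m.start, m.end) for m in tag_note(make_note(text))]
            upper = [(m.start, m.end) for m in tag_note(make_note(text.upper()))]
            assert spans == upper

    def test_adding_exclusion_never_adds_mentions(self):
        rng = np.random.default_rng(2)
        stricter = DEFAULT_PROTOCOL.with_exclusion("home_falls", r"\bfalls?\s+home\b")
        for i in range(100):
            note = make_note(random_text(rng))
            assert len(tag_note(note, stricter)) <= len(tag_note(note, DEFAULT_PROTOCOL))

    def test_matches_bruteforce_oracle_on_random_strings(self):
        rng = np.random.default_rng(3)
        for i in range(200):
            text = random_text(rng)
            got = [(m.start, m.end) for m in tag_note(make_note(text))]
            assert got == bruteforce_tag(text, DEFAULT_PROTOCOL), text


class TestFilterCorpus:
    def test_flag_counts(self):
        notes = [
            make_note("Patient fell overnight.", note_id="a"),
            make_note("No events.", note_id="b"),
            make_note("Vitals stable.", note_id="c"),
        ]
        flagged, summary = filter_corpus(notes)
        assert [n.note_id for n, _ in flagged] == ["a"]
        assert (summary.n_notes_flagged, summary.n_notes_unflagged) == (1, 2)

    def test_all_empty_notes(self):
        notes = [make_note("", note_id=f"n{i}") for i in range(4)]
        flagged, summary = filter_corpus(notes)
        assert flagged == [] and summary.n_notes_flagged == 0

    def test_patient_flag_proportion_tracks_generation_rate(self):
        # 25% of patients get one fall-word note; flagged-patient share must
        # land within binomial error of the generation rate.
        rng = np.random.default_rng(4)
        notes, n_patients = [], 400
        has_fall = rng.random(n_patients) < 0.25
        for i in range(n_patients):
            text = "Patient fell near the bed." if has_fall[i] else "Vitals stable."
            notes.append(make_note(text, note_id=f"n{i}", patient_id=f"p{i}"))
        _, summary = filter_corpus(notes)
        p_hat = summary.n_patients_flagged / n_patients
        se = (0.25 * 0.75 / n_patients) ** 0.5
        assert abs(p_hat - 0.25) <= 3 * se
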