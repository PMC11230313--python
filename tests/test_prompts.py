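"""Prompt construction, few-shot composition rules, label parsing, mock backend."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fallsift.backends import BackendError, MockBackend, classify
from fallsift.chunker import NoteChunk
from fallsift.prompts import (
    DEFAULT_FEW_SHOT_EXAMPLES,
    FEW_SHOT_TEMPLATE,
    ZERO_SHOT_TEMPLATE,
    ExampleSubcategory,
    FewShotExample,
    PromptMode,
    PromptTemplate,
    PromptValidationError,
    build_prompt,
    parse_label,
)
from fallsift.records import Label


def chunk_of(text: str, note_id: str = "n1") -> NoteChunk:
    return NoteChunk(note_id=note_id, text=text, mention_count=1, source_sentence_indices=(0,))


class TestBuildPrompt:
    def test_zero_shot_contains_chunk_exactly_once(self):
        text = "Patient fell today while walking."
        prompt = build_prompt(chunk_of(text), ZERO_SHOT_TEMPLATE)
        assert prompt.count(text) == 1

    def test_few_shot_examples_precede_chunk(self):
        text = "UNIQUE-CHUNK-SENTINEL sentence."
        prompt = build_prompt(chunk_of(text), FEW_SHOT_TEMPLATE, DEFAULT_FEW_SHOT_EXAMPLES)
        positions = [prompt.index(e.text) for e in DEFAULT_FEW_SHOT_EXAMPLES]
        assert all(p < prompt.index(text) for p in positions)

    def test_duplicate_positive_subcategories_rejected(self):
        bad = (
            FewShotExample("fell A", Label.POSITIVE, ExampleSubcategory.FALL_EVENT_TYPE_A),
            FewShotExample("fell B", Label.POSITIVE, ExampleSubcategory.FALL_EVENT_TYPE_A),
            FewShotExample("no fall", Label.NEGATIVE, ExampleSubcategory.NO_FALL),
        )
        with pytest.raises(PromptValidationError):
            build_prompt(chunk_of("x"), FEW_SHOT_TEMPLATE, bad)

    def test_wrong_example_count_rejected(self):
        with pytest.raises(PromptValidationError, match="3 examples"):
            build_prompt(chunk_of("x"), FEW_SHOT_TEMPLATE, DEFAULT_FEW_SHOT_EXAMPLES[:2])

    def test_zero_shot_rejects_examples(self):
        with pytest.raises(PromptValidationError):
            build_prompt(chunk_of("x"), ZERO_SHOT_TEMPLATE, DEFAULT_FEW_SHOT_EXAMPLES)

    def test_label_must_match_subcategory(self):
        with pytest.raises(PromptValidationError):
            FewShotExample("fell", Label.NEGATIVE, ExampleSubcategory.FALL_EVENT_TYPE_A)

    def test_template_requires_single_chunk_slot(self):
        with pytest.raises(PromptValidationError):
            PromptTemplate("bad", PromptMode.ZERO_SHOT, "no slot here")

    @given(st.text(min_size=1, max_size=40), st.text(min_size=1, max_size=40))
    def test_injective_on_chunk_text(self, a, b):
        if a == b:
            return
        pa = build_prompt(chunk_of(a), ZERO_SHOT_TEMPLATE)
        pb = build_prompt(chunk_of(b), ZERO_SHOT_TEMPLATE)
        assert pa != pb


class TestParseLabel:
    def test_explanation_then_trailing_one(self):
        raw = (
            "The patient fell while eating quiche, as indicated by “he then fell "
            "full after 5 bites and stopped.” This is a fall event. 1"
        )
        assert parse_label(raw) is Label.POSITIVE

    def test_explanation_then_trailing_zero(self):
        raw = (
            "The note mentions that the patient's pain started after a fall, but it "
            "does not specify whether the patient fell after surgery. 0"
        )
        assert parse_label(raw) is Label.NEGATIVE

    def test_no_label_token_abstains(self):
        assert parse_label("I cannot determine this.") is Label.ABSTAIN

    @pytest.mark.parametrize(
        "token, expected",
        [
            ("1", Label.POSITIVE),
            ("0", Label.NEGATIVE),
            ("yes", Label.POSITIVE),
            ("No", Label.NEGATIVE),
            ("fall event: yes", Label.POSITIVE),
            ("fall event: no", Label.NEGATIVE),
            ("fall event: positive", Label.POSITIVE),
            ("fall event: negative", Label.NEGATIVE),
        ],
    )
    def test_single_token_round_trip(self, token, expected):
        assert parse_label(f"Considering the evidence.\n{token}\n") is expected

    def test_digits_inside_numbers_ignored(self):
        assert parse_label("platelets fall < 50 and glucose 104") is Label.ABSTAIN

    def test_last_occurrence_wins_within_tier(self):
        assert parse_label("First guess 1 ... final answer 0") is Label.NEGATIVE

    def test_digit_tier_beats_yes_no(self):
        assert parse_label("yes, but the final verdict is 0") is Label.NEGATIVE


class TestMockBackend:
    def test_true_fall_template_classified_positive(self):
        chunk = chunk_of("Patient fell this morning while ambulating to the restroom.")
        prompt = build_prompt(chunk, ZERO_SHOT_TEMPLATE)
        response = classify(prompt, MockBackend(), note_id="n1")
        assert response.parsed_label is Label.POSITIVE
        assert response.explanation

    def test_historical_fall_classified_negative(self):
        chunk = chunk_of("Patient reported frequent falls at home prior to admission.")
        prompt = build_prompt(chunk, ZERO_SHOT_TEMPLATE)
        assert classify(prompt, MockBackend()).parsed_label is Label.NEGATIVE

    def test_five_runs_identical(self):
        prompt = build_prompt(chunk_of("Patient fell today."), ZERO_SHOT_TEMPLATE)
        backend = MockBackend(fnr=0.3, fpr=0.3, seed=5)
        responses = [classify(prompt, backend, run_index=i, note_id="n9") for i in range(5)]
        assert len({r.raw_text for r in responses}) == 1

    def test_empty_prompt_rejected(self):
        with pytest.raises(ValueError):
            classify("  ", MockBackend())

    def test_truth_map_overrides_rulebook(self):
        backend = MockBackend(truth={"n1": False})
        prompt = build_prompt(chunk_of("Patient fell today."), ZERO_SHOT_TEMPLATE)
        assert classify(prompt, backend, note_id="n1").parsed_label is Label.NEGATIVE
        with pytest.raises(BackendError):
            classify(prompt, backend, note_id="unknown")

    def test_flip_rates_recovered_over_many_notes(self):
        # With truth fixed, measured error rates converge on the configured
        # FNR/FPR within 3 binomial standard errors.
        n = 1500
        truth = {f"p{i}": True for i in range(n)} | {f"q{i}": False for i in range(n)}
        backend = MockBackend(fnr=0.10, fpr=0.05, seed=2, truth=truth)
        wrong_pos = sum(
            classify("prompt", backend, note_id=f"p{i}").parsed_label is Label.NEGATIVE
            for i in range(n)
        )
        wrong_neg = sum(
            classify("prompt", backend, note_id=f"q{i}").parsed_label is Label.POSITIVE
            for i in range(n)
        )
        se_fnr = (0.10 * 0.90 / n) ** 0.5
        se_fpr = (0.05 * 0.95 / n) ** 0.5
        assert abs(wrong_pos / n - 0.10) <= 3 * se_fnr
        assert abs(wrong_neg / n - 0.05) <= 3 * se_fpr
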