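"""Prompt construction and response parsing for the fall classifier.

Two prompting modes are supported:

* **zero-shot** — instructions only;
* **few-shot** — instructions plus exactly three in-context example notes:
  two containing *different types* of fall events and one containing no fall
  event.  Example composition is validated, not assumed.

The backend's reply is free text (an explanation plus a binary verdict, as
open-weight chat models produce); :func:`parse_label` extracts the verdict
with a documented token precedence and returns ``abstain`` when no label
token is found at all.  Abstentions are mapped to negative at evaluation
time but stay visible as a count.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .chunker import NoteChunk
from .records import Label


class PromptMode(str, Enum):
    ZERO_SHOT = "zero_shot"
    FEW_SHOT = "few_shot"


class PromptValidationError(ValueError):
    """Template or example-set violates the prompt contract."""


CHUNK_SLOT = "{chunk}"
EXAMPLES_SLOT = "{examples}"


@dataclass(frozen=True)
class PromptTemplate:
    """Instruction text with one chunk slot (and an examples slot if few-shot)."""

    name: str
    mode: PromptMode
    instruction_text: str
    example_slots: int = 0

    def __post_init__(self) -> None:
        if self.instruction_text.count(CHUNK_SLOT) != 1:
            raise PromptValidationError(
                f"template {self.name!r}: instruction_text must contain exactly one "
                f"{CHUNK_SLOT} slot"
            )
        expected = 3 if self.mode is PromptMode.FEW_SHOT else 0
        if self.example_slots != expected:
            raise PromptValidationError(
                f"template {self.name!r}: {self.mode.value} requires "
                f"{expected} example slots, got {self.example_slots}"
            )
        if self.mode is PromptMode.FEW_SHOT and EXAMPLES_SLOT not in self.instruction_text:
            raise PromptValidationError(
                f"template {self.name!r}: few-shot template needs an {EXAMPLES_SLOT} slot"
            )


class ExampleSubcategory(str, Enum):
    FALL_EVENT_TYPE_A = "fall_event_type_a"
    FALL_EVENT_TYPE_B = "fall_event_type_b"
    NO_FALL = "no_fall"


@dataclass(frozen=True)
class FewShotExample:
    text: str
    label: Label
    subcategory: ExampleSubcategory

    def __post_init__(self) -> None:
        positive = self.subcategory is not ExampleSubcategory.NO_FALL
        if positive and self.label is not Label.POSITIVE:
            raise PromptValidationError("fall-event example must carry a positive label")
        if not positive and self.label is not Label.NEGATIVE:
            raise PromptValidationError("no-fall example must carry a negative label")


def validate_examples(examples: Sequence[FewShotExample]) -> None:
    """Enforce the few-shot composition: 2 distinct fall-event types + 1 no-fall."""
    if len(examples) != 3:
        raise PromptValidationError(f"few-shot prompting requires exactly 3 examples, got {len(examples)}")
    subcats = [e.subcategory for e in examples]
    positives = [s for s in subcats if s is not ExampleSubcategory.NO_FALL]
    negatives = [s for s in subcats if s is ExampleSubcategory.NO_FALL]
    if len(negatives) != 1 or len(set(positives)) != 2:
        raise PromptValidationError(
            "examples must contain two fall events of different types and one "
            f"note without a fall event; got subcategories {[s.value for s in subcats]}"
        )


_DEFAULT_INSTRUCTION = (
    "You are reviewing an excerpt from a postsurgical clinical note. Decide "
    "whether the excerpt describes a fall event that happened to the patient "
    "during this care episode. A prior fall (history), fall-risk or "
    "fall-precaution language, and other uses of the word \"fall\" are NOT "
    "fall events. Reply with a one-sentence explanation followed by a single "
    "digit on its own line: 1 if the excerpt contains a fall event, 0 if it "
    "does not."
)

ZERO_SHOT_TEMPLATE = PromptTemplate(
    name="default_zero_shot",
    mode=PromptMode.ZERO_SHOT,
    instruction_text=_DEFAULT_INSTRUCTION + "\n\nNote excerpt:\n{chunk}\n",
)

FEW_SHOT_TEMPLATE = PromptTemplate(
    name="default_few_shot",
    mode=PromptMode.FEW_SHOT,
    instruction_text=(
        _DEFAULT_INSTRUCTION
        + "\n\nHere are three annotated examples:\n{examples}\n"
        + "Note excerpt:\n{chunk}\n"
    ),
    example_slots=3,
)


#: Default in-context example set: two fall events of different types (an
#: observed in-hospital fall and an unwitnessed found-down event) plus one
#: confounder note without a fall event.
DEFAULT_FEW_SHOT_EXAMPLES: tuple[FewShotExample, ...] = (
    FewShotExample(
        text=(
            "Patient fell this morning while ambulating to the restroom and "
            "was assisted back to bed."
        ),
        label=Label.POSITIVE,
        subcategory=ExampleSubcategory.FALL_EVENT_TYPE_A,
    ),
    FewShotExample(
        text=(
            "Patient was found down on the floor by his bed, having fallen "
            "while reaching for the call light."
        ),
        label=Label.POSITIVE,
        subcategory=ExampleSubcategory.FALL_EVENT_TYPE_B,
    ),
    FewShotExample(
        text="May need to transfuse if platelets fall < 50.",
        label=Label.NEGATIVE,
        subcategory=ExampleSubcategory.NO_FALL,
    ),
)


def _render_example(example: FewShotExample, position: int) -> str:
    digit = "1" if example.label is Label.POSITIVE else "0"
    return f"Example {position}:\n{example.text}\nAnswer: {digit}\n"


def build_prompt(
    chunk: NoteChunk,
    template: PromptTemplate,
    examples: Optional[Sequence[FewShotExample]] = None,
) -> str:
    """Render the final prompt string; byte-identical across calls."""
    if template.mode is PromptMode.ZERO_SHOT:
        if examples:
            raise PromptValidationError("zero-shot prompts take no examples")
        return template.instruction_text.replace(CHUNK_SLOT, chunk.text)
    if examples is None:
        raise PromptValidationError("few-shot prompts require examples")
    validate_examples(examples)
    rendered = "\n".join(_render_example(e, i + 1) for i, e in enumerate(examples))
    return template.instruction_text.replace(EXAMPLES_SLOT, rendered).replace(
        CHUNK_SLOT, chunk.text
    )


@dataclass(frozen=True)
class ModelResponse:
    """Raw backend text plus the parsed binary verdict."""

    raw_text: str
    parsed_label: Label
    explanation: str
    backend_name: str
    run_index: int


# Label-token precedence, highest first.  Within a tier the LAST occurrence
# wins; lower tiers are consulted only when no higher-tier token exists.
# Tier 1: a standalone digit 0/1 (not part of a number like "50" or "0.5").
# Tier 2: a standalone yes/no word.
# Tier 3: an explicit "fall event: yes/no" phrase.
_TIER_PATTERNS: tuple[tuple[str, re.Pattern, dict[str, Label]], ...] = (
    (
        "digit",
        re.compile(r"(?<![\w.])([01])(?![\w.])"),
        {"1": Label.POSITIVE, "0": Label.NEGATIVE},
    ),
    (
        "yes_no",
        re.compile(r"\b(yes|no)\b", re.IGNORECASE),
        {"yes": Label.POSITIVE, "no": Label.NEGATIVE},
    ),
    (
        "phrase",
        re.compile(r"fall event\s*[:=\-]\s*(yes|no|positive|negative)", re.IGNORECASE),
        {
            "yes": Label.POSITIVE,
            "positive": Label.POSITIVE,
            "no": Label.NEGATIVE,
            "negative": Label.NEGATIVE,
        },
    ),
)


def parse_label(raw_text: str) -> Label:
    """Extract the binary verdict from raw model output.

    Scans the precedence tiers in order and, within the first tier that
    matches, returns the label of the *last* occurrence.  No token in any
    tier -> ``abstain``.
    """
    for _, pattern, mapping in _TIER_PATTERNS:
        matches = pattern.findall(raw_text)
        if matches:
            return mapping[matches[-1].lower()]
    return Label.ABSTAIN


def split_explanation(raw_text: str) -> str:
    """Everything before the final label token, stripped; may be empty."""
    for _, pattern, _mapping in _TIER_PATTERNS:
        matches = list(pattern.finditer(raw_text))
        if matches:
            return raw_text[: matches[-1].start()].strip()
    return raw_text.strip()
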