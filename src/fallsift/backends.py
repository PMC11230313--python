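"""Classifier backend contract and the deterministic mock backend.

Real large-language-model adapters (local or cloud-hosted) plug in behind
the same one-method contract; the repository's own tests and pipelines use
:class:`MockBackend`, which emulates an instruction-following chat model:

* it decides a base label either from a supplied ground-truth mapping
  (``note_id -> bool``) or from a small rulebook of clinical-language cues;
* it flips the label with configurable false-negative / false-positive
  rates, using a hash keyed by (seed, note id or prompt) so the decision is
  stable across repeated runs — repeatability across run indices is a
  property of the backend, as observed with greedy decoding;
* it emits an explanation sentence followed by a standalone ``1``/``0``
  verdict, so the response parser is exercised end to end.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Protocol, Sequence, runtime_checkable

from .prompts import ModelResponse, parse_label, split_explanation


class BackendError(RuntimeError):
    """Transport-level backend failure (distinct from a parse failure)."""


@runtime_checkable
class Backend(Protocol):  # pragma: no cover - structural contract
    name: str

    def generate(self, prompt: str, *, note_id: Optional[str] = None, run_index: int = 0) -> str:
        ...


#: Ordered rulebook: first matching rule decides the base label.  Negative
#: cues (history, risk/precaution, figurative uses) are checked before the
#: generic fall-word rule, mirroring how the synthetic note families are
#: phrased; unmatched text defaults to negative.
DEFAULT_RULEBOOK: tuple[tuple[str, bool], ...] = (
    (r"history of|frequent falls at home|prior to admission|after a fall\b.{0,20}\bago", False),
    (r"fall risk|precaution|prevention", False),
    (r"platelets fall|fell full|niagara falls|pressure continued to fall|stocks? fell", False),
    (r"\bfound down\b|\bfallen\b|\bfell\b|sustained a fall|\bfall\b", True),
)


def _stable_unit(seed: int, key: str) -> float:
    """Uniform [0, 1) value from a platform-stable hash of (seed, key)."""
    digest = hashlib.sha256(f"{seed}|{key}".encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") / 2**64


@dataclass
class MockBackend:
    """Deterministic stand-in classifier with configurable error rates.

    ``fnr`` / ``fpr`` are the probabilities that a true-positive /
    true-negative input gets the wrong verdict.  When ``truth`` is given the
    base label is looked up by note id; otherwise the rulebook decides from
    the prompt text.  Identical (prompt, note_id) inputs yield identical
    output for every ``run_index``.
    """

    fnr: float = 0.0
    fpr: float = 0.0
    seed: int = 0
    truth: Optional[Mapping[str, bool]] = None
    rulebook: Sequence[tuple[str, bool]] = DEFAULT_RULEBOOK
    name: str = "mock"
    _compiled: list[tuple[re.Pattern, bool]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        for rate, label in ((self.fnr, "fnr"), (self.fpr, "fpr")):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {rate}")
        self._compiled = [
            (re.compile(pat, re.IGNORECASE), lab) for pat, lab in self.rulebook
        ]

    def _base_label(self, prompt: str, note_id: Optional[str]) -> bool:
        if self.truth is not None and note_id is not None:
            if note_id not in self.truth:
                raise BackendError(f"mock backend has no ground truth for note {note_id!r}")
            return bool(self.truth[note_id])
        # Rulebook mode reads only the note excerpt, not the instructions or
        # in-context examples (which themselves mention falls).
        target = prompt.rsplit("Note excerpt:", 1)[-1]
        for pattern, label in self._compiled:
            if pattern.search(target):
                return label
        return False

    def generate(self, prompt: str, *, note_id: Optional[str] = None, run_index: int = 0) -> str:
        base = self._base_label(prompt, note_id)
        rate = self.fnr if base else self.fpr
        flipped = rate > 0.0 and _stable_unit(self.seed, note_id or prompt) < rate
        verdict = base ^ flipped
        if verdict:
            explanation = (
                "The note describes the patient falling during this care episode, "
                "which is a fall event."
            )
        else:
            explanation = (
                "The note mentions the word fall but does not describe a new fall "
                "event for this patient during this care episode."
            )
        return f"{explanation}\n{'1' if verdict else '0'}"


def classify(
    prompt: str,
    backend: Backend,
    run_index: int = 0,
    note_id: Optional[str] = None,
) -> ModelResponse:
    """Send one prompt to a backend and parse the reply.

    An empty prompt is a caller error; transport failures surface as
    :class:`BackendError`; an unparseable reply is *not* an error — it comes
    back as an ``abstain`` label.
    """
    if not prompt or not prompt.strip():
        raise ValueError("prompt must be non-empty")
    raw = backend.generate(prompt, note_id=note_id, run_index=run_index)
    return ModelResponse(
        raw_text=raw,
        parsed_label=parse_label(raw),
        explanation=split_explanation(raw),
        backend_name=backend.name,
        run_index=run_index,
    )
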