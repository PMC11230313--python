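# Methods

This note documents the models, rules, and numerical choices behind
`fallsift`, and what the synthetic experiments do and do not demonstrate.

## Task and pipeline model

The task is binary detection of *fall events* — a patient actually falling
during the index postsurgical care episode — in free-text clinical notes.
Everything else that mentions falling is a negative: prior falls
(*history of falls*), risk/precaution language (*fall risk*), and other
uses of the word (*other mention*), plus notes with no fall content
(*no fall*). The five-way schema exists because the negatives are not
interchangeable: historical mentions are the dominant false-positive mode
for LLM classifiers on this task, so evaluation keeps the subcategories to
support error analysis.

The pipeline is a funnel: cohort selection → regex mention filter →
±1-sentence chunking → prompted classification → evaluation. The filter is
deliberately high-recall and low-precision; precision is the classifier's
responsibility.

## Cohort rules and boundary semantics

Inclusion: age at surgery ≥ 50 years; inpatient stay ≤ 90 days (inclusive);
no death within 30 days after surgery. "Within 30 days" is read so that a
death on day 30 excludes and day 31 does not; both boundaries are tested.
Only the earliest surgery per patient is retained (ties on date broken by
lowest record id), eligibility being checked per record before
deduplication. Cohort dates are compared at day resolution.

The note-selection window is (surgery date, discharge date] at day
resolution: the observation period is not standardised across systems, and
the inpatient stay is the defensible default — it is the period the
surgical team can act on, and it guarantees every selected note belongs to
the index encounter. The bound is configurable.

## Regex protocol

The default lexicon is word-boundary alternation over
`fall|falls|falling|fallen|fell` plus the phrase `found down`; exclusions
are `fall precaution(s)` and `fall(s) prevention`. Published clinical fall
regexes are site-extended artifacts, so the protocol is configuration (named
patterns, YAML-friendly), not a constant. Two scope decisions matter:

* **Exclusion scope is the sentence.** A mention is suppressed when any
  exclusion pattern matches anywhere in the sentence containing it. This
  keeps "Fall precautions in place." from flagging a note while still
  tagging "Patient later fell" in the next sentence.
* **Only precautions are excluded.** Fall-risk phrasing and figurative uses
  pass the filter on purpose: the annotation schema has categories for
  them, and the classifier must see them to be measured on them.

Overlapping matches resolve leftmost-longest, so mentions are disjoint and
sorted. The tagger is tested for exact agreement with a brute-force oracle
that attempts an anchored match at every character offset.

## Sentence splitting and chunking

The splitter is rule-based: terminal punctuation followed by whitespace or
end-of-text, newlines as hard boundaries, and a configurable guard list of
clinical abbreviations (Dr., Pt., q.i.d., ...). Deterministic and
dependency-light, it is adequate for template-like clinical prose;
sentences like "Transferred per Dr. Smith's order." do not split, while
initial-style fragments ("A. B.") do — erring toward shorter sentences,
which only shrinks context windows slightly. A trailing "etc." will also
not close a sentence; this is a known, accepted miss.

A chunk is the union of {i−1, i, i+1} windows over all mention sentences,
clipped to the document, deduplicated, in document order, joined with a
single space. Union rather than naive concatenation: overlapping windows
would otherwise duplicate sentences and distort the prompt. An optional
sentence cap (off by default) exists for context-limited backends.

## Prompt harness and response parsing

Prompt templates are plain strings with `{chunk}` (and `{examples}`)
slots. The default instruction asks for a one-sentence explanation followed
by a standalone `1`/`0` verdict — the response shape open-weight chat
models produce for this task. Few-shot prompts embed exactly three
examples, validated as two fall events of *different* types plus one
non-event; violating the composition is an error, not a warning.

Label parsing uses a three-tier precedence: standalone digit `0`/`1` (not
part of a larger number) > standalone yes/no > an explicit
"fall event: yes/no" phrase. Within the first tier that matches, the last
occurrence wins (models restate evidence before concluding). No token at
all parses as *abstain*; abstentions map to negative for metrics but are
reported as a count, so parse failures stay visible.

## Mock backend

The mock backend emulates a greedy-decoded instruction-following model.
Its base verdict comes either from a supplied ground-truth map
(`note_id → bool`) or from a small ordered rulebook of clinical cues
applied to the note excerpt (negative cues — history, risk/precaution,
figurative — checked before the generic fall-word rule). The verdict is
then flipped with probability FNR (true positives) or FPR (true negatives),
decided by a SHA-256 hash of (seed, note id), so errors are reproducible,
independent of evaluation order, and identical across run indices —
mirroring run-to-run repeatability of deterministic decoding. The reply
text routes through the same parser as any real backend's.

Real-model adapters implement the same one-method contract
(`generate(prompt, note_id=?, run_index=?) -> str`); nothing in the
repository requires them.

## Evaluation

For binary outputs the exact AUROC equals balanced accuracy,
(sensitivity + specificity)/2 — implemented as such and cross-checked in
tests against both a pairwise-concordance oracle and `sklearn`'s
`roc_auc_score`. The implied-AUROC reconstruction inverts printed
(precision, recall) under a known class balance using *continuous* tp/fp,
because printed metrics are rounded; demanding integer counts would make
most published rows unrepresentable. Reported values round half-away-from-
zero to 2 decimals in table-comparison mode; full precision is kept
internally. Undefined metrics (no gold positives/negatives) raise rather
than return silent zeros. Cohen's κ is computed over the five-way
categories by default (the granularity annotators actually work at), with a
binary option; both are reported by the agreement tool since published IAA
values do not state their granularity.

## Targeted sampling

Likely positive = note in (t_report, t_report + 24 h]; possibly positive =
[t_report − 30 d, t_report); likely negative = all notes of patients with
no report. "Within 24 hours" is read as *after* the report, and "one
month" fixed at 30 days (calendar-month arithmetic is ambiguous); both
windows are parameters. A note qualifying for both windows lands in likely
positive. Notes of reported patients outside both windows join no stratum
(likely negative is a patient-level definition) and are counted separately.
Draws are uniform without replacement from a seeded generator.

## Synthetic corpus

The generator emulates the *structure* of a postsurgical note stream, not
its surface realism: per-patient surgical admissions (8% deliberately
violating an inclusion rule, 5% with a second surgery, 15% with an
out-of-window note, so the cohort stage has real work); 1 + Poisson(2)
timestamped inpatient notes per patient; note text assembled from slot-
randomised paraphrase families for the five categories, sandwiched between
neutral filler sentences so chunk windows carry context. Defaults: 43.3%
fall events / 56.7% negatives (the internal gold-set composition), with the
negative mass concentrated on historical mentions, the dominant confounder.
Fall-event and confounder families always contain a lexicon word, so
regex recall on events is 1 and the classifier faces non-trivial negatives;
one fall-risk variant uses precaution phrasing and is correctly removed by
the filter. A configurable fraction (default 0.6) of fall events also emits
an official fall-report note at the event time, anchoring the targeted
sampler; patient-level ICD fall codes are assigned with configurable
sensitivity (0.77) and specificity (0.95) relative to true fall events,
emulating imperfect coding.

All randomness flows through one `numpy` generator in a fixed draw order:
a fixed seed reproduces the corpus byte for byte.

**What passing tests show** — that the machinery is correct: filters honour
their boundaries, the tagger and chunker equal brute-force oracles,
injected backend error rates come back out of the full pipeline within
binomial error, repeated runs are byte-identical. **What they do not
show** — anything about real notes: template sentences are far easier than
clinical prose, there is no spelling noise, no section headers, no
copy-forward, and the mock backend does not model an LLM's actual failure
modes. Published LLM operating points are reference inputs (used for the
implied-AUROC reconstruction), never reproduced.

## Problem sizes and defaults

Unit and property suites use hundreds of randomised cases per oracle
(1 000 random strings for the tagger, 500 placements for the chunker, 200
label sets for AUROC); the end-to-end recovery experiment uses 500 patients
(~2 000 notes, ~1 500 reaching the classifier), where three binomial
standard errors on recall/specificity are about ±0.02–0.03 — tight enough
to detect a mis-specified flip, small enough to run in seconds.
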