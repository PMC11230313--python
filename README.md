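# fallsift

**Postsurgical fall-event detection from free-text clinical notes.**

Falls are a leading cause of injury in older surgical patients, but most fall
events live only in the unstructured narrative of the electronic health
record: ICD fall codes miss the majority of them, and the word *fall* is
wildly ambiguous in clinical text ("fall precautions", "history of falls",
"platelets fall < 50", "trip to Niagara Falls"). `fallsift` implements a
complete detection pipeline for this problem, aimed at clinical-NLP
researchers and informatics teams who want to measure fall incidence after
surgery — or to benchmark an LLM classifier on the task — without shipping
protected notes anywhere:

1. **Cohort selection** — patients ≥ 50 years at surgery, inpatient stay
   ≤ 90 days, no death within 30 days of surgery, first surgery per patient;
   notes kept if dated strictly after surgery and up to discharge.
2. **Regex mention filter** — word-boundary forms of
   *fall/falls/fell/fallen/falling* plus *found down*, with sentence-scoped
   exclusion of fall-precaution boilerplate. Fall-risk language and
   figurative uses deliberately pass: disambiguating them is the
   classifier's job.
3. **Note chunking** — for every tagged mention, the sentence before, the
   mention sentence, and the sentence after; windows from multiple mentions
   are unioned in document order.
4. **Prompt harness** — zero-shot and few-shot (exactly three in-context
   examples: two fall events of different types, one non-event) prompts over
   a pluggable classifier backend. A deterministic mock backend with
   configurable false-negative/false-positive rates stands in for the LLM;
   its replies (explanation + `1`/`0` verdict) exercise the response parser
   end to end.
5. **Evaluation** — PPV (precision), recall (sensitivity), specificity,
   AUROC, Cohen's κ for inter-annotator agreement, and a false-positive
   breakdown over the five-way gold schema (*fall event*, *history of
   falls*, *fall risk*, *other mention*, *no fall*).
6. **Targeted sampling** — external-validation triage of notes into
   *likely positive* (≤ 24 h after an official fall report), *possibly
   positive* (≤ 30 d before one), and *likely negative* (patients with no
   report) strata, with seeded without-replacement draws.
7. **Synthetic corpus** — a generator for EHR-like patients, surgeries,
   notes across all five annotation categories, official fall reports, and
   imperfect ICD coding, with known ground truth, so the whole pipeline is
   testable with no data access.

## The core statistic

For a classifier that emits only a binary verdict, the ROC curve has a
single interior point, so its exact area reduces to balanced accuracy:

```
AUROC = (sensitivity + specificity) / 2
```

Given a published (PPV, recall) pair and the gold-set class balance
(n₊, n₋), the implied AUROC is recovered by inverting the confusion matrix
with continuous counts:

```
tp = recall · n₊        fp = tp · (1 − PPV) / PPV
specificity = (n₋ − fp) / n₋
AUROC = (recall + specificity) / 2
```

`fallsift report` applies this to the twelve published operating points of
three open-weight LLMs (LLaMA3-8B, Gemma-7B, Mixtral-8×7B, zero- and
few-shot, two health systems); eight of the twelve printed AUROC values are
recovered exactly at two decimals, and the remaining four differ only in the
final rounded digit.

## Worked example

Run the full pipeline on a synthetic corpus (~2 000 notes from 500
patients) with a mock backend that wrongly rejects 10% of true fall events
and wrongly accepts 5% of non-events:

```python
from fallsift.pipeline import run_pipeline

config = {
    "seed": 1,
    "simulate": {"n_patients": 500},
    "classify": {"backend": "mock", "mode": "zero_shot", "runs": 5,
                 "fnr": 0.10, "fpr": 0.05},
}
manifest = run_pipeline(config, "out/")
```

`out/eval_report.json` then contains (seed 1):

```
precision    0.9673
recall       0.9040
specificity  0.9507
auroc        0.9273
```

Read: of 1 536 regex-flagged notes reaching the classifier, measured recall
(0.904) and specificity (0.951) recover the injected error rates (0.90 and
0.95), and AUROC is their mean — the two-point identity. The five
`predictions_run*.jsonl` files are byte-identical, the repeatability
expected of a deterministic backend. The same stages are available as CLI
subcommands (`fallsift simulate | cohort | filter | chunk | classify |
sample | kappa | evaluate | run | report`).

## Limitations

The mock backend measures the *pipeline*, not language understanding: real
LLM adapters plug in behind the same one-method contract, and published
LLM operating points are treated as reference numbers, not reproduced. The
synthetic corpus is template-based and does not model real note length,
section structure, or site-specific documentation culture (see
`docs/methods.md`).
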