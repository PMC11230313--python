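"""Stage orchestration: simulate/load -> cohort -> filter -> chunk -> classify -> evaluate.

Every stage writes plain files (JSON-Lines / CSV) and is recorded in a
:class:`RunManifest` with input/output paths, in/out counts, the config
hash, and the seed, so a run is auditable and reproducible from its
manifest.  Stage handoff through files means an ``evaluate``-only invocation
on saved predictions gives the same report as the full run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping, Optional

from . import __version__
from .annotation import read_annotations_csv, to_binary
from .backends import MockBackend, classify
from .chunker import NoteChunk, build_note_chunk
from .cohort import apply_inclusion, select_postsurgical_notes
from .evaluation import ConfusionMatrix, EvalReport, evaluate, responses_to_binary
from .prompts import (
    DEFAULT_FEW_SHOT_EXAMPLES,
    FEW_SHOT_TEMPLATE,
    ZERO_SHOT_TEMPLATE,
    PromptMode,
    build_prompt,
)
from .records import (
    Label,
    read_notes_jsonl,
    read_surgeries_csv,
    write_notes_jsonl,
    write_surgeries_csv,
)
from .simulate import CorpusConfig, generate_corpus
from .tagger import DEFAULT_PROTOCOL, filter_corpus, write_mentions_csv


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and a sample of its input."""


@dataclass
class StageRecord:
    name: str
    inputs: list[str]
    outputs: list[str]
    n_in: int
    n_out: int


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str = ""
    stages: list[StageRecord] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "started": self.started,
            "finished": self.finished,
            "stages": [vars(s) for s in self.stages],
        }

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def config_hash(config: Mapping[str, Any]) -> str:
    """Hash of the canonical JSON form of the semantic config."""
    canonical = json.dumps(config, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


def write_chunks_jsonl(chunks: list[NoteChunk], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in chunks:
            fh.write(
                json.dumps(
                    {
                        "note_id": c.note_id,
                        "text": c.text,
                        "mention_count": c.mention_count,
                        "source_sentence_indices": list(c.source_sentence_indices),
                    }
                )
                + "\n"
            )


def read_chunks_jsonl(path: str | Path) -> list[NoteChunk]:
    chunks = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                chunks.append(
                    NoteChunk(
                        note_id=obj["note_id"],
                        text=obj["text"],
                        mention_count=obj["mention_count"],
                        source_sentence_indices=tuple(obj["source_sentence_indices"]),
                    )
                )
    return chunks


def write_predictions_jsonl(responses: list[dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for row in responses:
            fh.write(json.dumps(row, ensure_ascii=False) + "\n")


def read_predictions_jsonl(path: str | Path) -> dict[str, Label]:
    parsed: dict[str, Label] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                obj = json.loads(line)
                parsed[obj["note_id"]] = Label(obj["parsed_label"])
    return parsed


def _zero_report() -> EvalReport:
    return EvalReport(
        precision=float("nan"),
        recall=float("nan"),
        specificity=float("nan"),
        auroc=float("nan"),
        matrix=ConfusionMatrix(0, 0, 0, 0),
        abstain_count=0,
    )


def evaluate_predictions(
    predictions_path: str | Path,
    annotations_path: str | Path,
    report_path: Optional[str | Path] = None,
) -> EvalReport:
    """Score a saved prediction file against a gold annotation CSV."""
    parsed = read_predictions_jsonl(predictions_path)
    annotations = read_annotations_csv(annotations_path)
    covered = [a for a in annotations if a.note_id in parsed]
    if not covered:
        report = _zero_report()
    else:
        gold = [to_binary(a) for a in covered]
        preds, abstains = responses_to_binary({a.note_id: parsed[a.note_id] for a in covered})
        report = evaluate(preds, gold, abstain_count=abstains, gold_annotations=covered)
    if report_path is not None:
        report.write_json(report_path)
    return report


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline described by ``config`` under ``out_dir``.

    Config sections: ``simulate`` (generator parameters) *or* ``inputs``
    (paths to notes/surgeries/annotations), plus ``classify`` (backend, mode,
    runs, error rates).  ``seed`` feeds both the generator and the backend.
    Rerunning with the same config reproduces every artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(),
    )

    def run_stage(name, fn, *args, n_in=0):
        try:
            return fn(*args)
        except Exception as err:  # re-raise with stage context
            sample = str(args[0])[:120] if args else ""
            raise PipelineError(f"stage {name!r} failed on input {sample!r}: {err}") from err

    # -- stage: corpus ------------------------------------------------------
    if "simulate" in config:
        sim_cfg = CorpusConfig(**{**config["simulate"], "seed": seed})
        corpus = run_stage("simulate", generate_corpus, sim_cfg)
        corpus_paths = corpus.write(out / "corpus")
        notes, surgeries = corpus.notes, corpus.surgeries
        annotations = corpus.annotations
        truth = corpus.truth_by_note
        manifest.stages.append(
            StageRecord("simulate", [], sorted(corpus_paths.values()),
                        sim_cfg.n_patients, len(notes))
        )
    elif "inputs" in config:
        paths = config["inputs"]
        notes = read_notes_jsonl(paths["notes"])
        surgeries = read_surgeries_csv(paths["surgeries"])
        annotations = (
            read_annotations_csv(paths["annotations"]) if "annotations" in paths else []
        )
        truth = {to_binary(a).note_id: to_binary(a).label is Label.POSITIVE for a in annotations}
        manifest.stages.append(
            StageRecord("load", sorted(str(v) for v in paths.values()), [],
                        len(notes), len(notes))
        )
    else:
        raise PipelineError("config must contain a 'simulate' or an 'inputs' section")

    # -- stage: cohort ------------------------------------------------------
    cohort = run_stage("cohort", apply_inclusion, surgeries)
    selected = run_stage("cohort", select_postsurgical_notes, cohort, notes)
    write_surgeries_csv(cohort, out / "cohort.csv")
    write_notes_jsonl(selected, out / "selected_notes.jsonl")
    manifest.stages.append(
        StageRecord("cohort", [], [str(out / "cohort.csv"), str(out / "selected_notes.jsonl")],
                    len(notes), len(selected))
    )

    # -- stage: filter ------------------------------------------------------
    flagged, summary = run_stage("filter", filter_corpus, selected, DEFAULT_PROTOCOL)
    all_mentions = [m for _, ms in flagged for m in ms]
    write_mentions_csv(all_mentions, out / "mentions.csv")
    manifest.stages.append(
        StageRecord("filter", [], [str(out / "mentions.csv")],
                    summary.n_notes_in, summary.n_notes_flagged)
    )

    # -- stage: chunk -------------------------------------------------------
    chunks = [run_stage("chunk", build_note_chunk, note, ms) for note, ms in flagged]
    write_chunks_jsonl(chunks, out / "chunks.jsonl")
    manifest.stages.append(
        StageRecord("chunk", [], [str(out / "chunks.jsonl")], len(flagged), len(chunks))
    )

    # -- stage: classify ----------------------------------------------------
    clf_cfg = dict(config.get("classify", {}))
    backend_name = clf_cfg.get("backend", "mock")
    if backend_name != "mock":
        raise PipelineError(
            f"stage 'classify': unknown backend {backend_name!r} (plugins register "
            "their own Backend implementation)"
        )
    backend = MockBackend(
        fnr=float(clf_cfg.get("fnr", 0.0)),
        fpr=float(clf_cfg.get("fpr", 0.0)),
        seed=seed,
        truth=truth if clf_cfg.get("use_truth", True) else None,
    )
    mode = PromptMode(clf_cfg.get("mode", "zero_shot"))
    template = ZERO_SHOT_TEMPLATE if mode is PromptMode.ZERO_SHOT else FEW_SHOT_TEMPLATE
    examples = None if mode is PromptMode.ZERO_SHOT else DEFAULT_FEW_SHOT_EXAMPLES
    runs = int(clf_cfg.get("runs", 1))
    prediction_paths = []
    for run_index in range(runs):
        rows = []
        for chunk in chunks:
            prompt = build_prompt(chunk, template, examples)
            response = classify(prompt, backend, run_index=run_index, note_id=chunk.note_id)
            rows.append(
                {
                    "note_id": chunk.note_id,
                    "backend": response.backend_name,
                    "raw_text": response.raw_text,
                    "parsed_label": response.parsed_label.value,
                }
            )
        path = out / f"predictions_run{run_index}.jsonl"
        write_predictions_jsonl(rows, path)
        prediction_paths.append(str(path))
    manifest.stages.append(
        StageRecord("classify", [str(out / "chunks.jsonl")], prediction_paths,
                    len(chunks), len(chunks) * runs)
    )

    # -- stage: evaluate ----------------------------------------------------
    report_path = out / "eval_report.json"
    if annotations and chunks:
        report = evaluate_predictions(prediction_paths[0], out / "corpus" / "gold_annotations.csv"
                                      if "simulate" in config else config["inputs"]["annotations"])
    else:
        report = _zero_report()
    report.write_json(report_path)
    manifest.stages.append(
        StageRecord("evaluate", prediction_paths[:1], [str(report_path)],
                    len(chunks), 1)
    )

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.write(out / "manifest.json")
    return manifest
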