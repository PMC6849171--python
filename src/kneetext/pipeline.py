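"""End-to-end orchestration: responses file in, feature matrices,
question answers and evaluation reports out.

The system splits into two subsystems mirrored here: feature extraction
(parsing, sentiment, concept recognition, lexicon lookup combined into
per-question vectors; plus the concept-mention answers for Q1/Q2) and
classification/evaluation (per-question ordinal classifiers under k-fold
cross-validation, pooled confusion matrices, weighted P/R/F and summary
statistics).  Every run writes a manifest with config hash, seeds and
resource checksums so outputs can be reproduced byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .classify import (
    DEFAULT_QUESTION_SPECS,
    ClassifierSpec,
    CrossValidationPlan,
    cross_validate,
)
from .evaluate import (
    ConfusionMatrix,
    SummaryReport,
    round_half_up,
    summarize,
    weighted_metrics,
    write_results_csv,
)
from .features import (
    FeatureSchema,
    FeatureVector,
    LIKERT_QUESTIONS,
    Resources,
    default_schemas,
    extract_features,
    load_default_resources,
    schemas_from_yaml,
    vectors_to_frame,
)
from .ner import answer_open_question
from .preprocess import parse

logger = logging.getLogger(__name__)

QUESTION_TOPICS = {
    "Q1": "condition", "Q2": "treatment", "Q3": "changes", "Q4": "confidence",
    "Q5": "stiffness", "Q6": "pain", "Q7": "other symptoms",
    "Q8": "daily activities", "Q9": "other activities", "Q10": "other comments",
}


@dataclass
class PipelineConfig:
    resources: Resources = None  # type: ignore[assignment]
    schemas: dict[str, FeatureSchema] = field(default_factory=default_schemas)
    question_specs: dict[str, ClassifierSpec] = field(
        default_factory=lambda: dict(DEFAULT_QUESTION_SPECS)
    )
    cv: CrossValidationPlan = field(default_factory=CrossValidationPlan)
    ordinal: bool = True  # wrap learned methods in the ordinal decomposition
    log_level: str = "INFO"

    def __post_init__(self):
        if self.resources is None:
            self.resources = load_default_resources()
        for q in LIKERT_QUESTIONS:
            if q not in self.question_specs:
                raise ValueError(f"no classifier spec configured for {q}")
            if q not in self.schemas:
                raise ValueError(f"no feature schema configured for {q}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """YAML keys (all optional): ``schemas`` (path), ``methods``
        (question -> method name), ``cv`` ({k, stratified, seed}),
        ``ordinal``, ``log_level``."""
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "schemas" in raw:
            kwargs["schemas"] = {**default_schemas(), **schemas_from_yaml(raw["schemas"])}
        if "methods" in raw:
            specs = dict(DEFAULT_QUESTION_SPECS)
            for q, m in raw["methods"].items():
                specs[q.upper()] = ClassifierSpec(method=m)
            kwargs["question_specs"] = specs
        if "cv" in raw:
            kwargs["cv"] = CrossValidationPlan(**raw["cv"])
        for key in ("ordinal", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def spec_for(self, question_id: str) -> ClassifierSpec:
        spec = self.question_specs[question_id]
        if self.ordinal and spec.method != "sentiment-rule" and not spec.ordinal:
            spec = ClassifierSpec(
                method=spec.method,
                hyperparameters=spec.hyperparameters,
                ordinal=True,
                seed=spec.seed,
            )
        return spec


def read_responses(path: str | Path) -> tuple[list[dict], int]:
    """JSON-lines reader: one object per line with participant_id,
    question_id, text and optionally timestamp/gold.  Unparseable lines
    are logged and skipped; the skip count is returned for the manifest."""
    rows: list[dict] = []
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError:
                logger.warning("skipping unparseable line %d", lineno)
                skipped += 1
                continue
            if "_generator_seed" in obj:
                continue  # corpus header
            if not isinstance(obj, dict) or "question_id" not in obj or "text" not in obj:
                logger.warning("skipping malformed record on line %d", lineno)
                skipped += 1
                continue
            rows.append(obj)
    return rows, skipped


@dataclass
class ExtractionResult:
    vectors: dict[str, list[FeatureVector]]  # per Likert question
    open_answers: dict[str, list[dict]]      # Q1/Q2: response id -> mentions
    manifest: dict


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _resource_checksums() -> dict[str, str]:
    from .features import data_path

    out = {}
    base = data_path()
    for f in sorted(base.rglob("*.tsv")):
        out[str(f.relative_to(base))] = _sha256(f)
    return out


def run_extract(
    responses_path: str | Path,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
    timestamp: bool = True,
) -> ExtractionResult:
    """Feature-extraction subsystem over a JSON-lines responses file.

    Writes (when ``out_dir`` is given) one feature CSV per Likert
    question, a JSON file of normalized concept answers for Q1/Q2, and a
    run manifest.
    """
    config = config or PipelineConfig()
    rows, skipped = read_responses(responses_path)
    vectors: dict[str, list[FeatureVector]] = {q: [] for q in LIKERT_QUESTIONS}
    open_answers: dict[str, list[dict]] = {"Q1": [], "Q2": []}
    for row in rows:
        q = str(row["question_id"]).upper()
        rid = f"{row.get('participant_id', '?')}-{q}"
        text = str(row["text"])
        if not text.strip():
            logger.info("empty mandatory answer flagged for %s", rid)
        if q in ("Q1", "Q2"):
            doc = parse(text, response_id=rid)
            mentions = answer_open_question(doc, config.resources.minilexicon, q)
            open_answers[q].append(
                {
                    "response_id": rid,
                    "mentions": [
                        {
                            "text": m.text,
                            "concept_id": m.concept_id,
                            "semantic_type": m.semantic_type,
                            "char_start": m.char_start,
                            "char_end": m.char_end,
                        }
                        for m in mentions
                    ],
                }
            )
        elif q in vectors:
            gold = row.get("gold")
            vectors[q].append(
                extract_features(
                    text, q, config.schemas[q], config.resources,
                    response_id=rid, gold=int(gold) if gold is not None else None,
                )
            )
        else:
            logger.warning("unknown question id %r; skipped", q)
            skipped += 1

    manifest = {
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(
                {q: config.schemas[q].fingerprint for q in LIKERT_QUESTIONS}
                | {f"spec:{q}": config.question_specs[q].method for q in LIKERT_QUESTIONS},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16],
        "cv_seed": config.cv.seed,
        "resource_checksums": _resource_checksums(),
        "n_responses": len(rows),
        "n_skipped": skipped,
    }
    if timestamp:
        manifest["timestamp"] = datetime.now(timezone.utc).isoformat()

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for q in LIKERT_QUESTIONS:
            vectors_to_frame(vectors[q]).to_csv(out / f"features_{q}.csv", index=False)
        (out / "open_answers.json").write_text(json.dumps(open_answers, indent=2))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return ExtractionResult(vectors=vectors, open_answers=open_answers, manifest=manifest)


@dataclass
class EvaluationResult:
    confusion: dict[str, ConfusionMatrix]
    per_question: list  # (qid, P, R, F) on the 0-1 scale
    summary: SummaryReport


def run_evaluate(
    extraction: ExtractionResult,
    config: Optional[PipelineConfig] = None,
    out_dir: Optional[str | Path] = None,
) -> EvaluationResult:
    """Classification subsystem: per-question cross-validation, pooled
    confusion matrices, weighted P/R/F and the cross-question summary.
    Requires gold labels on every Likert question's vectors."""
    config = config or PipelineConfig()
    missing = [q for q in LIKERT_QUESTIONS if not extraction.vectors.get(q)]
    if missing:
        raise ValueError(f"no labelled features for question(s): {', '.join(missing)}")
    confusion: dict[str, ConfusionMatrix] = {}
    per_question = []
    for q in LIKERT_QUESTIONS:
        vecs = extraction.vectors[q]
        if any(v.gold is None for v in vecs):
            raise ValueError(f"gold labels missing for {q}")
        cm = cross_validate(vecs, config.spec_for(q), config.cv)
        confusion[q] = cm
        p, r, f = weighted_metrics(cm)
        per_question.append((q, p, r, f))
    summary = summarize(per_question)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "Question": q,
                "Topic": QUESTION_TOPICS[q],
                "Classes": 3,
                "Method": config.question_specs[q].method,
                "Features": config.schemas[q].length,
                "P (%)": p * 100,
                "R (%)": r * 100,
                "F (%)": f * 100,
            }
            for q, p, r, f in per_question
        ]
        write_results_csv(out / "results.csv", rows)
        (out / "summary.json").write_text(
            json.dumps(
                {
                    "per_question": {
                        q: {"P": p, "R": r, "F": f} for q, p, r, f in per_question
                    },
                    "f_measure": {
                        "mean_pct": round_half_up(summary.f_measure.mean * 100, 1),
                        "sd_pct": round_half_up(summary.f_measure.sd * 100, 1)
                        if summary.f_measure.sd is not None
                        else None,
                        "min_pct": round_half_up(summary.f_measure.min * 100, 1),
                        "max_pct": round_half_up(summary.f_measure.max * 100, 1),
                    },
                },
                indent=2,
            )
        )
    return EvaluationResult(confusion=confusion, per_question=per_question, summary=summary)
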