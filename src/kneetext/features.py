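"""Per-question feature assembly.

Each Likert-scale question (Q3-Q10) has a :class:`FeatureSchema`: an
ordered list of descriptors drawn from the pipeline's four evidence
sources (concept mentions, negation, graded modifiers, sentiment).  The
default schemas ship with the dimensionalities of the published system
configuration (Q3: 8, Q4: 8, Q5: 8, Q6: 10, Q7: 5, Q8: 14, Q9: 14); the
*identities* of the features behind those counts were never published, so
the compositions here are this package's own construction and can be
overridden via YAML (see :func:`schemas_from_yaml`).

Q10 (free comments) bypasses learned classification: the sentence-level
sentiment label, majority-voted over the response (ties -> neutral), is
the prediction.  A minimal sentiment-only schema is still provided so the
cross-validation machinery can treat Q10 uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources as _ilr
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml

from . import ner as _ner
from .context import (
    DEFAULT_NEUTRAL_BAND,
    PolarityLexicon,
    detect_negation,
    load_polarity_lexicon,
    score_sentiment,
)
from .lexicon import GradedLexicon, grade_for_headword, load_graded_lexicon_dir
from .ner import MiniLexicon, load_lexicon, recognize
from .preprocess import ParsedDocument, parse

LIKERT_QUESTIONS = ("Q3", "Q4", "Q5", "Q6", "Q7", "Q8", "Q9", "Q10")

#: ordinal class names per question, classes 1/2/3 in order
CLASS_SCHEMES: dict[str, tuple[str, str, str]] = {
    "Q3": ("worse", "same", "better"),
    "Q4": ("no", "reasonably", "fully"),
    "Q5": ("none", "some", "severe"),
    "Q6": ("none", "some", "severe"),
    "Q7": ("none", "some", "severe"),
    "Q8": ("not at all", "somewhat", "a lot"),
    "Q9": ("not at all", "somewhat", "a lot"),
    "Q10": ("negative", "neutral", "positive"),
}

SENTIMENT_CLASS_BY_LABEL = {"negative": 1, "neutral": 2, "positive": 3}

VALID_SOURCES = {
    "ner-count",
    "ner-negated-count",
    "grade-max",
    "negation-count",
    "sentiment-score",
    "sentiment-label",
    "keyword-flag",
}

ACTIVITY_TYPES = ("dora", "ocdi", "ocac", "prog")


@dataclass(frozen=True)
class QuestionScheme:
    question_id: str
    class_names: tuple[str, str, str]

    def name_of(self, label: int) -> str:
        return self.class_names[label - 1]


@dataclass(frozen=True)
class OrdinalLabel:
    value: int  # 1 | 2 | 3
    scheme: QuestionScheme

    def __post_init__(self):
        if self.value not in (1, 2, 3):
            raise ValueError(f"ordinal label must be 1/2/3, got {self.value}")


def scheme_for(question_id: str) -> QuestionScheme:
    q = question_id.upper()
    if q not in CLASS_SCHEMES:
        raise KeyError(f"no ordinal class scheme for {question_id!r}")
    return QuestionScheme(question_id=q, class_names=CLASS_SCHEMES[q])


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    source: str
    types: frozenset[str] = frozenset()     # for ner-count / ner-negated-count
    aspect: str = ""                        # for grade-max
    headwords: tuple[str, ...] = ()         # for grade-max
    keywords: tuple[str, ...] = ()          # for keyword-flag

    def __post_init__(self):
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown feature source {self.source!r}")

    @property
    def width(self) -> int:
        return 3 if self.source == "sentiment-label" else 1

    @property
    def column_names(self) -> list[str]:
        if self.source == "sentiment-label":
            return [f"{self.name}={lab}" for lab in ("negative", "neutral", "positive")]
        return [self.name]


@dataclass(frozen=True)
class FeatureSchema:
    question_id: str
    descriptors: tuple[FeatureDescriptor, ...]

    def __post_init__(self):
        names = [d.name for d in self.descriptors]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate descriptor names in schema {self.question_id}")

    @property
    def length(self) -> int:
        return sum(d.width for d in self.descriptors)

    @property
    def column_names(self) -> list[str]:
        cols: list[str] = []
        for d in self.descriptors:
            cols.extend(d.column_names)
        return cols

    @property
    def fingerprint(self) -> str:
        import hashlib

        payload = "|".join(
            f"{d.name}:{d.source}:{sorted(d.types)}:{d.aspect}:{d.headwords}:{d.keywords}"
            for d in self.descriptors
        )
        return hashlib.sha256((self.question_id + "#" + payload).encode()).hexdigest()[:16]


@dataclass
class FeatureVector:
    response_id: str
    question_id: str
    values: list[float]
    column_names: list[str]
    gold: Optional[int] = None  # ordinal label 1/2/3
    schema_fingerprint: str = ""

    def __post_init__(self):
        for v in self.values:
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError("feature values must be finite")


# ---------------------------------------------------------------------------
# Resources
# ---------------------------------------------------------------------------


@dataclass
class Resources:
    minilexicon: MiniLexicon
    graded: dict[str, GradedLexicon]
    polarity: PolarityLexicon
    neutral_band: float = DEFAULT_NEUTRAL_BAND


def data_path(*parts: str) -> Path:
    p = _ilr.files("kneetext").joinpath("data")
    for part in parts:
        p = p.joinpath(part)
    return Path(str(p))


def load_default_resources() -> Resources:
    return Resources(
        minilexicon=load_lexicon(data_path("minilexicon.tsv")),
        graded=load_graded_lexicon_dir(data_path("graded")),
        polarity=load_polarity_lexicon(data_path("polarity.tsv")),
    )


# ---------------------------------------------------------------------------
# Default schemas
# ---------------------------------------------------------------------------


def _d(name, source, **kw) -> FeatureDescriptor:
    if "types" in kw:
        kw["types"] = frozenset(kw["types"])
    if "headwords" in kw:
        kw["headwords"] = tuple(kw["headwords"])
    if "keywords" in kw:
        kw["keywords"] = tuple(kw["keywords"])
    return FeatureDescriptor(name=name, source=source, **kw)


SYMPTOM_HEADWORDS = {
    "Q5": ("stiffness", "stiff", "tightness"),
    "Q6": ("pain", "ache", "aching", "discomfort"),
    "Q7": (
        "swelling", "bruising", "clicking", "popping", "locking", "grinding",
        "instability", "numbness", "tingling", "weakness", "symptom",
        "catching", "soreness",
    ),
}

_LIMITATION_HEADWORDS = ("limit", "limited", "able", "unable", "restrict", "restricted", "struggle")


def default_schemas() -> dict[str, FeatureSchema]:
    """The shipped per-question schemas (dimensionalities as published)."""
    s: dict[str, FeatureSchema] = {}
    s["Q3"] = FeatureSchema("Q3", (
        _d("kw_worse", "keyword-flag", keywords=("worse", "worsen", "worsened", "deteriorate", "deteriorated")),
        _d("kw_same", "keyword-flag", keywords=("same", "unchanged", "similar", "stable", "change")),
        _d("kw_better", "keyword-flag", keywords=("better", "improve", "improved", "improving", "improvement")),
        _d("negation_count", "negation-count"),
        _d("sentiment_score", "sentiment-score"),
        _d("sentiment_label", "sentiment-label"),
    ))
    s["Q4"] = FeatureSchema("Q4", (
        _d("kw_low_confidence", "keyword-flag", keywords=("worried", "unsure", "nervous", "afraid", "anxious")),
        _d("kw_mid_confidence", "keyword-flag", keywords=("reasonably", "fairly", "somewhat", "quite", "moderately", "mostly")),
        _d("kw_high_confidence", "keyword-flag", keywords=("fully", "completely", "totally", "extremely", "very", "highly")),
        _d("kw_confident", "keyword-flag", keywords=("confident", "confidence")),
        _d("grade_confidence", "grade-max", aspect="confidence", headwords=("confident", "confidence")),
        _d("negation_count", "negation-count"),
        _d("sentiment_score", "sentiment-score"),
        _d("symptom_mentions", "ner-count", types={"sosy"}),
    ))
    for q in ("Q5", "Q6"):
        aspect = "stiffness" if q == "Q5" else "pain"
        base = [
            _d("symptom_mentions", "ner-count", types={"sosy"}),
            _d("negated_symptom_mentions", "ner-negated-count", types={"sosy"}),
            _d(f"grade_{aspect}", "grade-max", aspect=aspect, headwords=SYMPTOM_HEADWORDS[q]),
            _d("negation_count", "negation-count"),
            _d("sentiment_score", "sentiment-score"),
            _d("sentiment_label", "sentiment-label"),
        ]
        if q == "Q6":
            base.append(_d("kw_absence", "keyword-flag", keywords=("pain-free", "painless")))
            base.append(_d("anatomy_mentions", "ner-count", types={"anat"}))
        s[q] = FeatureSchema(q, tuple(base))
    s["Q7"] = FeatureSchema("Q7", (
        _d("symptom_mentions", "ner-count", types={"sosy"}),
        _d("negated_symptom_mentions", "ner-negated-count", types={"sosy"}),
        _d("grade_symptoms", "grade-max", aspect="symptoms", headwords=SYMPTOM_HEADWORDS["Q7"]),
        _d("negation_count", "negation-count"),
        _d("sentiment_score", "sentiment-score"),
    ))
    for q in ("Q8", "Q9"):
        s[q] = FeatureSchema(q, (
            _d("dora_mentions", "ner-count", types={"dora"}),
            _d("ocdi_mentions", "ner-count", types={"ocdi"}),
            _d("ocac_mentions", "ner-count", types={"ocac"}),
            _d("prog_mentions", "ner-count", types={"prog"}),
            _d("negated_activity_mentions", "ner-negated-count", types=set(ACTIVITY_TYPES)),
            _d("grade_limitation", "grade-max", aspect="limitation", headwords=_LIMITATION_HEADWORDS),
            _d("negation_count", "negation-count"),
            _d("sentiment_score", "sentiment-score"),
            _d("sentiment_label", "sentiment-label"),
            _d("kw_unaffected", "keyword-flag", keywords=("unaffected", "normal", "normally", "fine")),
            _d("kw_somewhat", "keyword-flag", keywords=("somewhat", "slightly", "occasionally", "partly", "bit")),
            _d("kw_a_lot", "keyword-flag", keywords=("completely", "severely", "totally", "greatly", "massively", "lot")),
        ))
    s["Q10"] = FeatureSchema("Q10", (
        _d("sentiment_score", "sentiment-score"),
        _d("sentiment_label", "sentiment-label"),
    ))
    return s


def schemas_from_yaml(path: str | Path) -> dict[str, FeatureSchema]:
    """Load per-question schemas from a YAML file of the form

    .. code-block:: yaml

        Q6:
          - {name: symptom_mentions, source: ner-count, types: [sosy]}
          - {name: grade_pain, source: grade-max, aspect: pain, headwords: [pain, ache]}
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict[str, FeatureSchema] = {}
    for qid, desc_list in raw.items():
        descs = []
        for d in desc_list:
            descs.append(
                FeatureDescriptor(
                    name=d["name"],
                    source=d["source"],
                    types=frozenset(d.get("types", [])),
                    aspect=d.get("aspect", ""),
                    headwords=tuple(d.get("headwords", [])),
                    keywords=tuple(d.get("keywords", [])),
                )
            )
        out[str(qid).upper()] = FeatureSchema(str(qid).upper(), tuple(descs))
    return out


# ---------------------------------------------------------------------------
# Extraction
# ---------------------------------------------------------------------------


def _response_sentiment(doc: ParsedDocument, res: Resources) -> tuple[float, str]:
    """Mean sentence score and majority label (ties -> neutral)."""
    if not doc.sentences:
        return 0.0, "neutral"
    pols = [
        score_sentiment(s, res.polarity, sentence_index=si, neutral_band=res.neutral_band)
        for si, s in enumerate(doc.sentences)
    ]
    mean = sum(p.score for p in pols) / len(pols)
    counts = {"negative": 0, "neutral": 0, "positive": 0}
    for p in pols:
        counts[p.label] += 1
    best = max(counts.values())
    winners = [lab for lab, c in counts.items() if c == best]
    label = winners[0] if len(winners) == 1 else "neutral"
    return mean, label


def predict_sentiment_class(doc: ParsedDocument, res: Resources) -> int:
    """Rule prediction for Q10: majority sentence polarity mapped onto the
    negative/neutral/positive scheme (1/2/3)."""
    _, label = _response_sentiment(doc, res)
    return SENTIMENT_CLASS_BY_LABEL[label]


def extract_features(
    text: str,
    question_id: str,
    schema: FeatureSchema,
    resources: Resources,
    response_id: str = "",
    gold: Optional[int] = None,
) -> FeatureVector:
    """Run parsing, concept recognition, negation, grading and sentiment
    over one response and fill the schema's descriptors in order.

    Counts are summed over sentences; grade-max aggregates by maximum
    severity and sentiment by mean score / majority label.  Deterministic
    for fixed resources.
    """
    q = question_id.upper()
    if q != schema.question_id:
        raise ValueError(f"schema is for {schema.question_id}, not {q}")
    for d in schema.descriptors:
        if d.source == "grade-max" and d.aspect not in resources.graded:
            raise KeyError(f"aspect lexicon {d.aspect!r} required by schema {q} is not loaded")

    doc = parse(text, response_id=response_id)
    mentions = recognize(doc, resources.minilexicon)
    negated_by_sentence = {
        si: {m.token_index for m in detect_negation(sent, si)}
        for si, sent in enumerate(doc.sentences)
    }
    # distinct cues, not marked tokens: one "no" negating two words is one negation
    cue_total = len(
        {
            (si, m.cue_index)
            for si, sent in enumerate(doc.sentences)
            for m in detect_negation(sent, si)
        }
    )
    sent_score, sent_label = _response_sentiment(doc, resources)

    def mention_negated(m: _ner.ConceptMention) -> bool:
        negs = negated_by_sentence.get(m.sentence_index, set())
        return any(t in negs for t in range(m.start, m.end))

    values: list[float] = []
    for d in schema.descriptors:
        if d.source == "ner-count":
            values.append(float(sum(1 for m in mentions if m.semantic_type in d.types)))
        elif d.source == "ner-negated-count":
            values.append(
                float(
                    sum(
                        1
                        for m in mentions
                        if m.semantic_type in d.types and mention_negated(m)
                    )
                )
            )
        elif d.source == "grade-max":
            g = grade_for_headword(doc, d.headwords, resources.graded[d.aspect])
            values.append(float(g) if g is not None else 0.0)
        elif d.source == "negation-count":
            values.append(float(cue_total))
        elif d.source == "sentiment-score":
            values.append(sent_score)
        elif d.source == "sentiment-label":
            values.extend(
                [1.0 if sent_label == lab else 0.0 for lab in ("negative", "neutral", "positive")]
            )
        elif d.source == "keyword-flag":
            kws = {k.lower() for k in d.keywords}
            flag = 0.0
            for si, sent in enumerate(doc.sentences):
                negs = negated_by_sentence.get(si, set())
                for tok in sent.tokens:
                    if (tok.lemma.lower() in kws or tok.surface.lower() in kws) and tok.index not in negs:
                        flag = 1.0
            values.append(flag)
    assert len(values) == schema.length
    return FeatureVector(
        response_id=response_id,
        question_id=q,
        values=values,
        column_names=schema.column_names,
        gold=gold,
        schema_fingerprint=schema.fingerprint,
    )


def vectors_to_frame(vectors: Sequence[FeatureVector]):
    """Feature matrix as a DataFrame: one row per response, header =
    descriptor column names plus the gold label column."""
    import pandas as pd

    if not vectors:
        return pd.DataFrame()
    cols = vectors[0].column_names
    data = {"response_id": [v.response_id for v in vectors]}
    for j, c in enumerate(cols):
        data[c] = [v.values[j] for v in vectors]
    data["gold"] = [v.gold if v.gold is not None else "" for v in vectors]
    return pd.DataFrame(data)
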