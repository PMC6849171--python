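"""Context analysis: explicit syntactic negation and sentence sentiment.

Negation detection covers *explicit syntactic* negation only — an overt
cue word (``not``, ``no``, ``never`` ...) whose scope is recovered from the
dependency graph.  Implicit/pragmatic negation (e.g. the verb *to ease*
effectively negating *pain*) is out of scope; the sentiment scorer
partially compensates because such verbs can carry lexicon polarity.

Rule inventory (applied in order, each producing :class:`NegationMark`\\ s):

R1   a negating adverb/particle (*not*, *n't*, *never*, *hardly*, *barely*)
     attached by ``advmod`` marks its head;
R2   a negative determiner (*no*, *neither*, *none*) attached by ``det``
     marks its nominal head;
R3   if a copular/linking verb is marked, the negation propagates to its
     nominal/adjectival subject (``nsubj``) and predicate (``attr``) — so
     in "The pain is not constant." both *pain* and *constant* end up
     marked;
R4   a marked nominal propagates to its adjectival modifiers (``amod``),
     so "no constant pain" also cancels *constant*.

Sentiment is a pluggable scorer; the default sums a graded polarity
lexicon over tokens, flips the sign of tokens negated by the rules above,
and normalizes the result into [-1, +1].
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .preprocess import Sentence

logger = logging.getLogger(__name__)

NEG_ADV_LEMMAS = frozenset({"not", "n't", "never", "hardly", "barely"})
NEG_DET_LEMMAS = frozenset({"no", "neither", "none"})
LINKING_LEMMAS = frozenset({"be", "seem", "feel", "look", "become", "get", "stay", "remain"})

DEFAULT_NEUTRAL_BAND = 0.1


@dataclass(frozen=True)
class NegationMark:
    sentence_index: int
    token_index: int
    cue_index: int
    rule: str  # R1..R4


@dataclass(frozen=True)
class SentencePolarity:
    sentence_index: int
    label: str  # negative | neutral | positive
    score: float  # in [-1, +1]


def detect_negation(
    sentence: Sentence,
    sentence_index: int = 0,
    rules: Optional[set[str]] = None,
) -> set[NegationMark]:
    """Apply rules R1-R4 to one parsed sentence.

    Pure and deterministic; returns a possibly empty set of marks.  The
    optional ``rules`` set disables rules not listed (config hook).
    """
    enabled = rules if rules is not None else {"R1", "R2", "R3", "R4"}
    marks: set[NegationMark] = set()
    toks = sentence.tokens
    marked: dict[int, tuple[int, str]] = {}  # token -> (cue, rule)

    def mark(tok: int, cue: int, rule: str) -> None:
        if tok not in marked:
            marked[tok] = (cue, rule)

    # R1: negating adverb marks its head
    if "R1" in enabled:
        for e in sentence.edges:
            if e.relation == "advmod" and toks[e.dependent].lemma in NEG_ADV_LEMMAS:
                if e.head >= 0:
                    mark(e.head, e.dependent, "R1")
    # R2: negative determiner marks its nominal head
    if "R2" in enabled:
        for e in sentence.edges:
            if e.relation == "det" and toks[e.dependent].lemma in NEG_DET_LEMMAS:
                if e.head >= 0 and toks[e.head].pos in {"NOUN", "PROPN", "PRON"}:
                    mark(e.head, e.dependent, "R2")
    # R3: marked linking verb propagates to subject and predicate
    if "R3" in enabled:
        for tok, (cue, _) in list(marked.items()):
            if toks[tok].lemma in LINKING_LEMMAS and toks[tok].pos in {"AUX", "VERB"}:
                for rel in ("nsubj", "attr"):
                    for child in sentence.children(tok, rel):
                        if toks[child].pos in {"NOUN", "PROPN", "PRON", "ADJ"}:
                            mark(child, cue, "R3")
    # R4: marked nominal propagates to its adjectival modifiers
    if "R4" in enabled:
        for tok, (cue, _) in list(marked.items()):
            if toks[tok].pos in {"NOUN", "PROPN"}:
                for child in sentence.children(tok, "amod"):
                    if toks[child].pos == "ADJ":
                        mark(child, cue, "R4")

    for tok, (cue, rule) in marked.items():
        marks.add(NegationMark(sentence_index=sentence_index, token_index=tok, cue_index=cue, rule=rule))
    return marks


def negated_token_indices(sentence: Sentence, sentence_index: int = 0) -> set[int]:
    return {m.token_index for m in detect_negation(sentence, sentence_index)}


# ---------------------------------------------------------------------------
# Sentiment
# ---------------------------------------------------------------------------


@dataclass
class PolarityLexicon:
    """term (lemma) -> polarity score in [-1, +1]"""

    scores: dict[str, float] = field(default_factory=dict)

    def __contains__(self, lemma: str) -> bool:
        return lemma.lower() in self.scores

    def get(self, lemma: str) -> float:
        return self.scores.get(lemma.lower(), 0.0)


def load_polarity_lexicon(path: str | Path) -> PolarityLexicon:
    """TSV: term \\t score, score in [-1, 1]; header optional."""
    scores: dict[str, float] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or len(row) < 2:
                continue
            term = row[0].strip().lower()
            if term in {"term", ""}:
                continue
            try:
                score = float(row[1])
            except ValueError:
                logger.warning("skipping malformed polarity row %r", row)
                continue
            if not -1.0 <= score <= 1.0:
                raise ValueError(f"polarity score out of range for {term!r}: {score}")
            scores[term] = score
    return PolarityLexicon(scores=scores)


class SentimentScorer:
    """Scorer contract: callable on a parsed sentence, returning a
    :class:`SentencePolarity`.  The neural model the architecture allows
    for can be plugged in here; the default is lexicon-based."""

    def score(self, sentence: Sentence, sentence_index: int = 0) -> SentencePolarity:  # pragma: no cover
        raise NotImplementedError


class LexiconSentimentScorer(SentimentScorer):
    """Sum of term polarities over tokens, sign-flipped for tokens negated
    by the explicit-negation rules, normalized by the number of polar
    tokens hit (hence bounded in [-1, +1])."""

    def __init__(self, lexicon: PolarityLexicon, neutral_band: float = DEFAULT_NEUTRAL_BAND):
        self.lexicon = lexicon
        self.neutral_band = neutral_band

    def score(self, sentence: Sentence, sentence_index: int = 0) -> SentencePolarity:
        negated = negated_token_indices(sentence, sentence_index)
        total = 0.0
        hits = 0
        for tok in sentence.tokens:
            s = self.lexicon.get(tok.lemma)
            if s == 0.0:
                continue
            hits += 1
            total += -s if tok.index in negated else s
        score = total / hits if hits else 0.0
        score = max(-1.0, min(1.0, score))
        if abs(score) < self.neutral_band:
            label = "neutral"
        else:
            label = "positive" if score > 0 else "negative"
        return SentencePolarity(sentence_index=sentence_index, label=label, score=score)


def score_sentiment(
    sentence: Sentence,
    lexicon: PolarityLexicon,
    sentence_index: int = 0,
    neutral_band: float = DEFAULT_NEUTRAL_BAND,
    scorer: Optional[SentimentScorer] = None,
) -> SentencePolarity:
    """Score one sentence with the given scorer (default lexicon-based)."""
    sc = scorer or LexiconSentimentScorer(lexicon, neutral_band=neutral_band)
    return sc.score(sentence, sentence_index)
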