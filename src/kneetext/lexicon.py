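"""Graded modifier lexicons and PMI collocation extraction.

A graded lexicon maps modifiers of one symptom aspect (pain, stiffness,
...) onto the 3-point severity scale used throughout the pipeline
(1 = none-level, 2 = some, 3 = severe); e.g. *mild* < *severe*, and
*sharp* counts as severe.  Modifiers implying absence (*pain-free*) carry
grade 1.

Candidate modifiers for such lexicons are induced corpus-linguistically:
:func:`extract_collocates` scores words co-occurring with a target word in
any supplied plain-text corpus by pointwise mutual information,

    PMI(c, t) = log2( N * f(c,t) / (f(c) * f(t)) ),

where f(c,t) counts co-occurrences within a +/-``window`` token distance
inside sentences, f(.) are corpus frequencies and N is the corpus size in
tokens.  The curation of the ranked list into grades is manual by design
(it is small and needs no medical expertise).
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .context import negated_token_indices, LINKING_LEMMAS
from .preprocess import ParsedDocument, Sentence, parse

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 5
DEFAULT_POS_FILTER = frozenset({"ADJ"})


@dataclass
class GradedLexicon:
    """aspect headword family -> {modifier: grade in {1,2,3}}"""

    aspect: str
    grades: dict[str, int] = field(default_factory=dict)

    def grade(self, modifier: str) -> Optional[int]:
        return self.grades.get(modifier.lower())

    def __contains__(self, modifier: str) -> bool:
        return modifier.lower() in self.grades


def load_graded_lexicon(path: str | Path, aspect: Optional[str] = None) -> GradedLexicon:
    """TSV ``modifier \\t grade`` with header; grades must be 1, 2 or 3.

    Duplicate modifiers: last row wins with a warning.  A grade outside
    {1,2,3} is a hard error.
    """
    path = Path(path)
    name = aspect or path.stem
    grades: dict[str, int] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or len(row) < 2 or row[0].strip().lower() in {"modifier", ""}:
                continue
            mod = row[0].strip().lower()
            try:
                g = int(row[1])
            except ValueError:
                raise ValueError(f"unparseable grade {row[1]!r} for modifier {mod!r} in {path}")
            if g not in {1, 2, 3}:
                raise ValueError(f"grade out of range for {mod!r} in {path}: {g}")
            if mod in grades:
                logger.warning("duplicate modifier %r in %s; last value wins", mod, path)
            grades[mod] = g
    return GradedLexicon(aspect=name, grades=grades)


def load_graded_lexicon_dir(path: str | Path) -> dict[str, GradedLexicon]:
    """Load every ``*.tsv`` in a directory, keyed by aspect (file stem)."""
    out: dict[str, GradedLexicon] = {}
    for f in sorted(Path(path).glob("*.tsv")):
        out[f.stem] = load_graded_lexicon(f)
    return out


def _modifier_candidates(sentence: Sentence, head_index: int) -> list[int]:
    """Token indices that modify the headword: adjectival modifiers,
    immediately preceding adjectives/adverbs, and copular predicates
    linked to the headword when it is the subject."""
    cands = set(sentence.children(head_index, "amod"))
    if head_index > 0 and sentence.tokens[head_index - 1].pos in {"ADJ", "ADV"}:
        cands.add(head_index - 1)
    # predicate adjectives across a copula: "The pain is (not) constant."
    head = None
    try:
        head = sentence.head_of(head_index)
    except KeyError:
        pass
    if (
        head is not None
        and head >= 0
        and sentence.relation_of(head_index) == "nsubj"
        and sentence.tokens[head].lemma in LINKING_LEMMAS
    ):
        for child in sentence.children(head, "attr"):
            if sentence.tokens[child].pos == "ADJ":
                cands.add(child)
    return sorted(cands)


def lookup_grade(
    head_index: int,
    sentence: Sentence,
    lex: GradedLexicon,
    sentence_index: int = 0,
) -> Optional[int]:
    """Maximum grade over the headword's graded modifiers, skipping
    modifiers cancelled by explicit negation; None when no graded,
    non-negated modifier is present."""
    negated = negated_token_indices(sentence, sentence_index)
    best: Optional[int] = None
    for ci in _modifier_candidates(sentence, head_index):
        if ci in negated:
            continue
        tok = sentence.tokens[ci]
        g = lex.grade(tok.lemma) or lex.grade(tok.surface)
        if g is not None and (best is None or g > best):
            best = g
    return best


def grade_for_headword(
    doc: ParsedDocument,
    headwords: Iterable[str],
    lex: GradedLexicon,
) -> Optional[int]:
    """Max :func:`lookup_grade` over every occurrence of any headword
    lemma in the document; None if no graded modifier anywhere."""
    heads = {h.lower() for h in headwords}
    best: Optional[int] = None
    for si, sent in enumerate(doc.sentences):
        for tok in sent.tokens:
            if tok.lemma.lower() in heads:
                g = lookup_grade(tok.index, sent, lex, sentence_index=si)
                if g is not None and (best is None or g > best):
                    best = g
    return best


# ---------------------------------------------------------------------------
# PMI collocation extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CollocationRow:
    collocate: str
    joint_count: int
    collocate_count: int
    target_count: int
    corpus_size: int
    pmi: float


@dataclass
class CollocationTable:
    target: str
    window: int
    pos_filter: frozenset[str]
    rows: list[CollocationRow] = field(default_factory=list)

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["collocate", "joint_count", "collocate_count", "target_count", "corpus_size", "pmi"])
            for r in self.rows:
                w.writerow([r.collocate, r.joint_count, r.collocate_count, r.target_count, r.corpus_size, f"{r.pmi:.6f}"])


def pmi(joint: int, f_c: int, f_t: int, n: int) -> float:
    """log2( N * f(c,t) / (f(c) * f(t)) ); requires all counts positive."""
    if joint <= 0 or f_c <= 0 or f_t <= 0 or n <= 0:
        raise ValueError("PMI requires positive counts")
    return math.log2(n * joint / (f_c * f_t))


def extract_collocates(
    corpus: str | ParsedDocument | Iterable[Sentence],
    target: str,
    window: int = DEFAULT_WINDOW,
    pos_filter: Optional[Iterable[str]] = DEFAULT_POS_FILTER,
) -> CollocationTable:
    """Count lemma co-occurrences with ``target`` within ``window`` tokens
    inside sentences and score them by PMI.

    ``pos_filter`` keeps only collocates whose POS is in the set (None =
    all non-punctuation tokens).  Rows with zero joint count are omitted;
    rows are sorted by PMI descending, then alphabetically.  A target
    absent from the corpus yields an empty table with a warning.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if isinstance(corpus, str):
        sentences: list[Sentence] = parse(corpus).sentences
    elif isinstance(corpus, ParsedDocument):
        sentences = corpus.sentences
    else:
        sentences = list(corpus)
    pos_set = frozenset(pos_filter) if pos_filter is not None else None
    tgt = target.lower()

    freq: dict[str, int] = {}
    joint: dict[str, int] = {}
    n_tokens = 0
    f_t = 0
    for sent in sentences:
        toks = [t for t in sent.tokens if t.pos != "PUNCT"]
        lemmas = [t.lemma.lower() for t in toks]
        n_tokens += len(toks)
        for lem in lemmas:
            freq[lem] = freq.get(lem, 0) + 1
            if lem == tgt:
                f_t += 1
        for i, lem in enumerate(lemmas):
            if lem != tgt:
                continue
            lo, hi = max(0, i - window), min(len(lemmas), i + window + 1)
            for j in range(lo, hi):
                if j == i:
                    continue
                if pos_set is not None and toks[j].pos not in pos_set:
                    continue
                if lemmas[j] == tgt:
                    continue
                joint[lemmas[j]] = joint.get(lemmas[j], 0) + 1

    table = CollocationTable(target=target, window=window, pos_filter=pos_set or frozenset())
    if f_t == 0:
        logger.warning("target %r not found in corpus", target)
        return table
    rows = [
        CollocationRow(
            collocate=c,
            joint_count=jc,
            collocate_count=freq[c],
            target_count=f_t,
            corpus_size=n_tokens,
            pmi=pmi(jc, freq[c], f_t, n_tokens),
        )
        for c, jc in joint.items()
        if jc > 0
    ]
    rows.sort(key=lambda r: (-r.pmi, r.collocate))
    table.rows = rows
    return table
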