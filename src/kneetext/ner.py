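"""Dictionary-based named-entity recognition with concept normalization.

Concepts live in a mini-lexicon with the structure of a large biomedical
terminology: every concept has a unique identifier, one or more synonym
names, and a semantic type code.  Matching is greedy leftmost-longest over
lemmas, case-insensitive, and never emits nested or overlapping mentions.
The module provides the final answers for the two open-ended questions
about the knee condition (Q1) and its treatment (Q2), and auxiliary
mention-count features for the Likert-scale questions.

Semantic type codes used by the bundled lexicon:

====== ==============================================
cond   medical condition / diagnosis
proc   surgical or therapeutic procedure
anat   anatomical structure
drug   medication
devi   device / aid
exac   exercise activity prescribed as treatment
sosy   sign or symptom
dora   daily or recreational activity
ocdi   occupation or discipline
ocac   occupational activity
prog   professional or occupational group
====== ==============================================
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .preprocess import ParsedDocument, lemmatize_phrase

logger = logging.getLogger(__name__)

Q1_TYPES = frozenset({"cond", "proc", "anat"})
Q2_TYPES = frozenset({"proc", "drug", "devi", "exac"})


@dataclass(frozen=True)
class LexiconEntry:
    concept_id: str
    name: str
    semantic_type: str


@dataclass(frozen=True)
class ConceptMention:
    """A recognized span normalized to a concept id.

    ``start``/``end`` are token indices within the sentence (half-open);
    ``char_start``/``char_end`` are offsets into the raw response text.
    """

    response_id: str
    sentence_index: int
    start: int
    end: int
    text: str
    concept_id: str
    semantic_type: str
    char_start: int = 0
    char_end: int = 0


@dataclass
class MiniLexicon:
    entries: list[LexiconEntry] = field(default_factory=list)
    # first lemma of a name -> list of (lemma tuple, entry, file order)
    _index: dict[str, list[tuple[tuple[str, ...], LexiconEntry, int]]] = field(
        default_factory=dict, repr=False
    )
    _by_name: dict[tuple[str, ...], str] = field(default_factory=dict, repr=False)

    def add(self, entry: LexiconEntry) -> None:
        lemmas = lemmatize_phrase(entry.name)
        if not lemmas:
            return
        order = len(self.entries)
        self.entries.append(entry)
        self._index.setdefault(lemmas[0], []).append((lemmas, entry, order))
        self._by_name.setdefault(lemmas, entry.concept_id)

    @property
    def concept_ids(self) -> set[str]:
        return {e.concept_id for e in self.entries}

    def names_of(self, concept_id: str) -> list[str]:
        return [e.name for e in self.entries if e.concept_id == concept_id]

    def candidates(self, first_lemma: str):
        return self._index.get(first_lemma, [])


def load_lexicon(path: str | Path) -> MiniLexicon:
    """Read a concept lexicon from TSV with header columns
    ``concept_id``, ``name``, ``semantic_type`` (extra columns ignored).

    Duplicate (name, semantic_type) rows are collapsed with a warning; an
    empty file yields an empty lexicon with a warning; a missing required
    column is a hard error naming the column.
    """
    lex = MiniLexicon()
    seen: set[tuple[str, str]] = set()
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            logger.warning("lexicon file %s is empty", path)
            return lex
        for col in ("concept_id", "name", "semantic_type"):
            if col not in reader.fieldnames:
                raise ValueError(f"lexicon {path} is missing required column {col!r}")
        nrows = 0
        for row in reader:
            cid = (row.get("concept_id") or "").strip()
            name = (row.get("name") or "").strip()
            styp = (row.get("semantic_type") or "").strip()
            if not cid or not name or not styp:
                logger.warning("skipping malformed lexicon row %r", row)
                continue
            key = (name.lower(), styp)
            if key in seen:
                logger.warning("duplicate lexicon row collapsed: %s/%s", name, styp)
                continue
            seen.add(key)
            lex.add(LexiconEntry(concept_id=cid, name=name, semantic_type=styp))
            nrows += 1
        if nrows == 0:
            logger.warning("lexicon file %s contained no usable rows", path)
    return lex


def recognize(
    doc: ParsedDocument,
    lex: MiniLexicon,
    types: Optional[Iterable[str]] = None,
) -> list[ConceptMention]:
    """Greedy leftmost-longest dictionary matching over lemmas.

    ``types`` restricts matches to the given semantic type codes (empty or
    None = all types).  Returned mentions are non-overlapping and ordered
    by text position; ties between equal-length overlapping matches are
    broken by lexicon file order.
    """
    wanted = set(types) if types else None
    out: list[ConceptMention] = []
    for si, sent in enumerate(doc.sentences):
        lemmas = [t.lemma.lower() for t in sent.tokens]
        i = 0
        n = len(lemmas)
        while i < n:
            best: Optional[tuple[int, int, LexiconEntry]] = None  # (length, order, entry)
            for name_lemmas, entry, order in lex.candidates(lemmas[i]):
                if wanted is not None and entry.semantic_type not in wanted:
                    continue
                L = len(name_lemmas)
                if i + L <= n and tuple(lemmas[i : i + L]) == name_lemmas:
                    cand = (L, -order, entry)
                    if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                        best = cand
            if best is not None:
                L, _, entry = best
                toks = sent.tokens[i : i + L]
                out.append(
                    ConceptMention(
                        response_id=doc.response_id,
                        sentence_index=si,
                        start=i,
                        end=i + L,
                        text=doc.text[toks[0].start : toks[-1].end],
                        concept_id=entry.concept_id,
                        semantic_type=entry.semantic_type,
                        char_start=toks[0].start,
                        char_end=toks[-1].end,
                    )
                )
                i += L
            else:
                i += 1
    return out


def normalize(name: str, lex: MiniLexicon) -> Optional[str]:
    """Case-insensitive synonym lookup: every synonym name of a concept
    maps to the same concept id; unknown names map to None."""
    if not name:
        raise ValueError("name must be non-empty")
    return lex._by_name.get(lemmatize_phrase(name))


def answer_open_question(
    doc: ParsedDocument, lex: MiniLexicon, question: str
) -> list[ConceptMention]:
    """Final named-entity answer for the open questions.

    Q1 (current condition) returns condition, procedure and anatomy
    mentions; Q2 (current treatment) returns procedure, drug, device and
    exercise-activity mentions.  Mentions come back in text order.
    """
    q = question.upper()
    if q == "Q1":
        types: frozenset[str] = Q1_TYPES
    elif q == "Q2":
        types = Q2_TYPES
    else:
        raise ValueError(f"answer_open_question handles Q1/Q2 only, got {question!r}")
    return recognize(doc, lex, types)


# ---------------------------------------------------------------------------
# Inline-XML gold annotations
# ---------------------------------------------------------------------------

# default mapping from inline tag names to semantic type codes; bare type
# codes (dora, ocdi, ...) pass through unchanged
DEFAULT_TAG_MAP = {"ne1": "cond", "ne2": "proc", "ne3": "anat"}

_TAG_RE = re.compile(r"<(/?)([A-Za-z][A-Za-z0-9]*)>")


@dataclass(frozen=True)
class GoldSpan:
    char_start: int
    char_end: int
    text: str
    semantic_type: str


def read_inline_xml(
    annotated: str, tag_map: Optional[dict[str, str]] = None
) -> tuple[str, list[GoldSpan]]:
    """Strip inline annotation tags, returning plain text plus gold spans
    with offsets into that plain text.  Tags must be non-nested."""
    tmap = dict(DEFAULT_TAG_MAP)
    if tag_map:
        tmap.update(tag_map)
    plain: list[str] = []
    spans: list[GoldSpan] = []
    pos = 0
    plain_len = 0
    open_tag: Optional[tuple[str, int]] = None
    for m in _TAG_RE.finditer(annotated):
        chunk = annotated[pos : m.start()]
        plain.append(chunk)
        plain_len += len(chunk)
        closing, tag = m.group(1) == "/", m.group(2).lower()
        if not closing:
            if open_tag is not None:
                raise ValueError(f"nested annotation tag <{tag}> inside <{open_tag[0]}>")
            open_tag = (tag, plain_len)
        else:
            if open_tag is None or open_tag[0] != tag:
                raise ValueError(f"unmatched closing tag </{tag}>")
            start = open_tag[1]
            text = "".join(plain)[start:plain_len]
            spans.append(
                GoldSpan(
                    char_start=start,
                    char_end=plain_len,
                    text=text,
                    semantic_type=tmap.get(tag, tag),
                )
            )
            open_tag = None
        pos = m.end()
    if open_tag is not None:
        raise ValueError(f"unclosed annotation tag <{open_tag[0]}>")
    plain.append(annotated[pos:])
    return "".join(plain), spans


def write_inline_xml(
    text: str,
    spans: Sequence[GoldSpan],
    tag_map: Optional[dict[str, str]] = None,
) -> str:
    """Insert inline tags at the given character spans (maximal-extent,
    non-nested); overlapping spans are rejected."""
    tmap = dict(DEFAULT_TAG_MAP)
    if tag_map:
        tmap.update(tag_map)
    inverse = {v: k for k, v in tmap.items()}
    ordered = sorted(spans, key=lambda s: s.char_start)
    prev_end = -1
    for s in ordered:
        if s.char_start < prev_end:
            raise ValueError("overlapping gold spans cannot be serialized")
        if not (0 <= s.char_start <= s.char_end <= len(text)):
            raise ValueError("gold span outside text bounds")
        prev_end = s.char_end
    out: list[str] = []
    pos = 0
    for s in ordered:
        tag = inverse.get(s.semantic_type, s.semantic_type)
        out.append(text[pos : s.char_start])
        out.append(f"<{tag}>{text[s.char_start:s.char_end]}</{tag}>")
        pos = s.char_end
    out.append(text[pos:])
    return "".join(out)


def mentions_to_gold(mentions: Sequence[ConceptMention]) -> list[GoldSpan]:
    return [
        GoldSpan(
            char_start=m.char_start,
            char_end=m.char_end,
            text=m.text,
            semantic_type=m.semantic_type,
        )
        for m in mentions
    ]
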