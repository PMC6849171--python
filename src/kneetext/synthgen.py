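"""Seeded generator of labelled synthetic questionnaire responses.

The real study data (short first-person free-text answers to a 10-item
open-ended knee questionnaire) is private, so every stage of the pipeline
is exercised on synthetic responses instead.  Templates per question
follow the ordinal class semantics the pipeline targets (change verbs for
Q3, confidence phrases for Q4, symptom + graded modifier for Q5-Q7,
activity limitation with named-entity slots for Q8-Q9, polar comments for
Q10); named-entity slots are filled from the bundled mini-lexicon, so the
gold label and gold entity annotations are consistent with the text by
construction.

Controllable knobs: class distribution over {1,2,3}; negation rate (the
probability that a class-1/absence response is phrased with an explicit
negation cue rather than an absence word); lexical noise rate driving
three operators (character typo in a non-entity word, synonym swap within
a concept, neutral distractor-sentence insertion); and the sentences-per-
response range.  All randomness flows through one seeded source, so a
fixed seed reproduces the corpus byte for byte.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .features import CLASS_SCHEMES, LIKERT_QUESTIONS
from .ner import GoldSpan, MiniLexicon, write_inline_xml

ALL_QUESTIONS = ("Q1", "Q2") + LIKERT_QUESTIONS


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_per_question: int = 55
    class_distribution: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    negation_rate: float = 0.5
    noise_rate: float = 0.05
    sentences_per_response: tuple[int, int] = (1, 2)
    questions: tuple[str, ...] = ALL_QUESTIONS

    def __post_init__(self):
        if self.n_per_question < 1:
            raise ValueError("n_per_question must be >= 1")
        if abs(sum(self.class_distribution) - 1.0) > 1e-9 or min(self.class_distribution) < 0:
            raise ValueError("class_distribution must be a probability vector")
        if not 0.0 <= self.negation_rate <= 1.0:
            raise ValueError("negation_rate must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must be in [0, 1]")
        lo, hi = self.sentences_per_response
        if not 1 <= lo <= hi:
            raise ValueError("sentences_per_response must be a valid range")


@dataclass
class SyntheticResponse:
    response_id: str
    participant_id: str
    question_id: str
    text: str
    gold: Optional[int]  # ordinal class 1/2/3; None for Q1/Q2
    template_id: str = ""
    ne_spans: list[GoldSpan] = field(default_factory=list)
    slot_fills: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Slots and templates
# ---------------------------------------------------------------------------

# slot name -> (semantic type, canonical lexicon names to draw from)
SLOT_DEFS: dict[str, tuple[str, tuple[str, ...]]] = {
    "cond": ("cond", ("osteoarthritis", "meniscus tear", "tendonitis", "bursitis",
                      "ACL rupture", "sprained knee", "ligament damage", "cartilage damage")),
    "anat": ("anat", ("knee", "ACL", "meniscus", "kneecap", "cartilage", "hamstring")),
    "proc": ("proc", ("reconstruction surgery", "arthroscopy", "knee replacement",
                      "physiotherapy", "meniscus repair")),
    "treat": ("proc", ("physiotherapy", "physio", "hydrotherapy", "massage")),
    "drug": ("drug", ("ibuprofen", "paracetamol", "naproxen", "painkillers")),
    "devi": ("devi", ("knee brace", "crutches", "knee support", "ice pack")),
    "exac": ("exac", ("squats", "stretches", "leg raises", "strengthening exercises", "step ups")),
    "symptom": ("sosy", ("swelling", "clicking", "popping", "bruising", "grinding",
                         "numbness", "tingling", "locking", "instability")),
    "symptom2": ("sosy", ("weakness", "tenderness", "catching", "warmth", "buckling")),
    "act": ("dora", ("walking", "shopping", "driving", "gardening", "housework",
                     "cooking", "climbing stairs")),
    "act2": ("dora", ("cycling", "swimming", "dog walking", "running")),
    "sport": ("dora", ("squash", "golf", "football", "tennis", "yoga", "badminton")),
    "sport2": ("dora", ("swimming", "cycling", "running", "gym")),
    "prog": ("prog", ("vehicle mechanic", "nurse", "teacher", "builder", "plumber", "carer")),
}

_SLOT_RE = re.compile(r"\{(\w+)\}")


@dataclass(frozen=True)
class Template:
    template_id: str
    text: str
    negated: bool = False  # carries an explicit negation cue


# class-keyed templates for the Likert questions; None key = unlabelled (Q1/Q2)
TEMPLATES: dict[str, dict[Optional[int], list[Template]]] = {
    "Q1": {None: [
        Template("q1a", "I am currently being treated for {cond}."),
        Template("q1b", "I have {cond} in my {anat}."),
        Template("q1c", "I completely ruptured my {anat} and had {proc}."),
        Template("q1d", "I was diagnosed with {cond} last year."),
        Template("q1e", "The doctors are not sure yet, but they think it is {cond}.", negated=True),
    ]},
    "Q2": {None: [
        Template("q2a", "I am having {treat} and doing {exac} every day."),
        Template("q2b", "I take {drug} and wear a {devi} when it flares up."),
        Template("q2c", "Mostly {treat}, plus {drug} when needed."),
        Template("q2d", "I use a {devi} and do {exac} twice a week."),
        Template("q2e", "I am not taking {drug} any more, just doing {exac}.", negated=True),
    ]},
    "Q3": {
        1: [
            Template("q3w1", "My knee has got worse this week."),
            Template("q3w2", "Things have deteriorated since my last entry."),
            Template("q3w3", "My knee has not improved at all; it feels worse.", negated=True),
        ],
        2: [
            Template("q3s1", "My knee feels much the same as last week."),
            Template("q3s2", "The condition is stable and unchanged."),
            Template("q3s3", "No real change this week, it is about the same.", negated=True),
        ],
        3: [
            Template("q3b1", "My knee is much better this week."),
            Template("q3b2", "Things have improved since my last entry."),
            Template("q3b3", "The knee keeps improving and feels better every day."),
        ],
    },
    "Q4": {
        1: [
            Template("q4n1", "I feel worried and unsure about my knee."),
            Template("q4n2", "I am not confident about looking after my knee.", negated=True),
            Template("q4n3", "I have no confidence in the knee at the moment.", negated=True),
        ],
        2: [
            Template("q4r1", "I feel reasonably confident about looking after my knee."),
            Template("q4r2", "Fairly confident, though I am still careful with it."),
            Template("q4r3", "I am somewhat confident about managing it now."),
        ],
        3: [
            Template("q4f1", "I am fully confident about looking after my knee."),
            Template("q4f2", "Very confident about managing my knee now."),
            Template("q4f3", "I feel completely confident with the {exac}."),
        ],
    },
    "Q5": {
        1: [
            Template("q5n1", "No stiffness when {act} this week.", negated=True),
            Template("q5n2", "I have not had any stiffness this week.", negated=True),
            Template("q5n3", "My knee has been loose and easy, with nothing to report."),
        ],
        2: [
            Template("q5s1", "Some mild stiffness in the morning."),
            Template("q5s2", "Slight stiffness after sitting for a while."),
            Template("q5s3", "Occasional stiffness when {act}."),
        ],
        3: [
            Template("q5v1", "Severe stiffness all day, especially in the morning."),
            Template("q5v2", "Constant stiffness that makes it hard to move."),
            Template("q5v3", "The stiffness has been terrible and persistent."),
        ],
    },
    "Q6": {
        1: [
            Template("q6n1", "No pain when {act} this week.", negated=True),
            Template("q6n2", "I have had no pain at all.", negated=True),
            Template("q6n3", "I have been completely pain-free this week."),
        ],
        2: [
            Template("q6s1", "Intermittent pain around the joint."),
            Template("q6s2", "Occasional dull pain after {act}."),
            Template("q6s3", "Some mild pain when {act}, nothing serious."),
        ],
        3: [
            Template("q6v1", "Constant pain whether sitting or standing."),
            Template("q6v2", "Severe sharp pain when {act}."),
            Template("q6v3", "The pain was unbearable at times this week."),
        ],
    },
    "Q7": {
        1: [
            Template("q7n1", "No {symptom} or other symptoms this week.", negated=True),
            Template("q7n2", "I have not noticed any {symptom}.", negated=True),
            Template("q7n3", "My knee has settled completely this week."),
        ],
        2: [
            Template("q7s1", "Some mild {symptom} after exercise."),
            Template("q7s2", "Slight {symptom} now and then."),
            Template("q7s3", "Occasional {symptom} in the evening."),
        ],
        3: [
            Template("q7v1", "Severe {symptom} most of the week."),
            Template("q7v2", "Constant {symptom} and significant {symptom2}."),
            Template("q7v3", "Bad {symptom} that keeps me awake at night."),
        ],
    },
    "Q8": {
        1: [
            Template("q8n1", "My knee has not limited my daily tasks at all.", negated=True),
            Template("q8n2", "I have managed {act} and {act2} normally."),
            Template("q8n3", "Day to day life has carried on as normal."),
        ],
        2: [
            Template("q8s1", "Somewhat limited when {act}; {act2} is slightly harder."),
            Template("q8s2", "Slightly limited with {act} this week."),
            Template("q8s3", "I managed most tasks but {act} was occasionally limited."),
        ],
        3: [
            Template("q8v1", "Severely limited this week; {act} and {act2} were a real struggle."),
            Template("q8v2", "My daily tasks were completely limited, even {act}."),
            Template("q8v3", "Greatly limited: I could not manage {act} at all.", negated=True),
        ],
    },
    "Q9": {
        1: [
            Template("q9n1", "My knee has not limited my work or hobbies at all.", negated=True),
            Template("q9n2", "I played {sport} and {sport2} as normal."),
            Template("q9n3", "Work and exercise carried on as normal this week."),
        ],
        2: [
            Template("q9s1", "Slightly limited at work and with {sport}."),
            Template("q9s2", "I had to cut back somewhat on {sport} and {sport2}."),
            Template("q9s3", "My job was occasionally limited, and {sport} was slightly harder."),
        ],
        3: [
            Template("q9v1", "My work as a {prog} was completely limited and I could not play {sport} at all.", negated=True),
            Template("q9v2", "Severely limited: no {sport} or {sport2}, and my job suffered badly.", negated=True),
            Template("q9v3", "I was greatly limited at work and had to give up {sport} entirely."),
        ],
    },
    "Q10": {
        1: [
            Template("q10n1", "I am frustrated and disappointed; the knee still hurts a lot."),
            Template("q10n2", "The treatment seems useless and I feel miserable."),
            Template("q10n3", "It has been an awful week and I am very unhappy."),
            Template("q10n4", "The treatment is not helping at all and I feel miserable.", negated=True),
        ],
        2: [
            Template("q10m1", "My next appointment is in two weeks."),
            Template("q10m2", "I have been using the {devi} as instructed."),
            Template("q10m3", "Nothing further to add this week.", negated=True),
        ],
        3: [
            Template("q10p1", "The physio has been brilliant and I am delighted with my progress."),
            Template("q10p2", "I feel great and very happy with the treatment."),
            Template("q10p3", "Everything is going well and I am really pleased."),
        ],
    },
}

# neutral fillers: no entity names, no polar or graded vocabulary
FILLER_SENTENCES = (
    "I will mention it at my next appointment.",
    "My next review is booked for next month.",
    "I have followed the advice from the clinic.",
    "I will keep an eye on it over the coming week.",
)

# the comments question is classified by majority sentence polarity, so
# its continuation sentences keep the comment's polarity instead of
# diluting it with neutral filler
Q10_FILLERS: dict[int, tuple[str, ...]] = {
    1: (
        "It has been a hard week and I feel unhappy about it.",
        "I am disappointed with how slowly it is going.",
    ),
    2: FILLER_SENTENCES[:2],
    3: (
        "I am really pleased with how it is going.",
        "Things feel better every week and I am grateful.",
    ),
}

_STOPWORDS = {
    "this", "that", "with", "when", "have", "been", "about", "after",
    "most", "every", "week", "knee", "from", "your", "their",
}


def _fill_template(
    tpl: Template,
    lex: MiniLexicon,
    rng: random.Random,
    noise_rate: float,
) -> tuple[str, list[GoldSpan], dict]:
    """Substitute slots, tracking entity character spans.  With
    probability ``noise_rate`` a slot is filled with a non-canonical
    synonym of the same concept (synonym-swap noise)."""
    out: list[str] = []
    spans: list[GoldSpan] = []
    fills: dict = {}
    pos = 0
    plain_len = 0
    for m in _SLOT_RE.finditer(tpl.text):
        lead = tpl.text[pos : m.start()]
        out.append(lead)
        plain_len += len(lead)
        slot = m.group(1)
        styp, names = SLOT_DEFS[slot]
        name = rng.choice(names)
        from .ner import normalize

        cid = normalize(name, lex)
        if cid is not None and rng.random() < noise_rate:
            synonyms = [n for n in lex.names_of(cid) if n.lower() != name.lower()]
            if synonyms:
                name = rng.choice(synonyms)
        out.append(name)
        spans.append(
            GoldSpan(char_start=plain_len, char_end=plain_len + len(name), text=name, semantic_type=styp)
        )
        fills[slot] = name
        plain_len += len(name)
        pos = m.end()
    tail = tpl.text[pos:]
    out.append(tail)
    return "".join(out), spans, fills


def _typo(text: str, spans: Sequence[GoldSpan], rng: random.Random) -> str:
    """Swap two adjacent inner characters of one content word outside any
    entity span (length-preserving, so spans stay valid)."""
    protected = [(s.char_start, s.char_end) for s in spans]
    candidates = []
    for m in re.finditer(r"[A-Za-z]{4,}", text):
        if m.group(0).lower() in _STOPWORDS:
            continue
        if any(s < m.end() and m.start() < e for s, e in protected):
            continue
        candidates.append(m)
    if not candidates:
        return text
    m = rng.choice(candidates)
    i = rng.randrange(m.start() + 1, m.end() - 2) if m.end() - m.start() > 3 else m.start() + 1
    chars = list(text)
    chars[i], chars[i + 1] = chars[i + 1], chars[i]
    return "".join(chars)


def generate(config: GeneratorConfig, lex: Optional[MiniLexicon] = None) -> list[SyntheticResponse]:
    """Generate ``n_per_question`` responses for each configured question.

    Reproducible under a fixed seed.  Class-3 responses draw grade-3
    modifiers, class-1 responses draw negated symptom mentions (with
    probability ``negation_rate``) or absence phrasings, class-2 sits in
    between; entity slots are filled from the mini-lexicon.
    """
    if lex is None:
        from .features import load_default_resources

        lex = load_default_resources().minilexicon
    rng = random.Random(config.seed)
    out: list[SyntheticResponse] = []
    dist = config.class_distribution
    for q in config.questions:
        qu = q.upper()
        if qu not in TEMPLATES:
            raise KeyError(f"no templates for question {q!r}")
        by_class = TEMPLATES[qu]
        labelled = None not in by_class
        for i in range(config.n_per_question):
            pid = f"P{i + 1:03d}"
            if labelled:
                u = rng.random()
                gold = 1 if u < dist[0] else (2 if u < dist[0] + dist[1] else 3)
                pool = by_class[gold]
            else:
                gold = None
                pool = by_class[None]
            # negation_rate picks between cue-bearing and cue-free templates
            neg_pool = [t for t in pool if t.negated]
            pos_pool = [t for t in pool if not t.negated]
            if neg_pool and (not pos_pool or rng.random() < config.negation_rate):
                tpl = rng.choice(neg_pool)
            else:
                tpl = rng.choice(pos_pool or neg_pool)
            text, spans, fills = _fill_template(tpl, lex, rng, config.noise_rate)
            # continuation / distractor sentence insertion
            fillers = Q10_FILLERS[gold] if qu == "Q10" and gold else FILLER_SENTENCES
            lo, hi = config.sentences_per_response
            extra = rng.randint(lo, hi) - 1
            for _ in range(extra):
                text = text + " " + rng.choice(fillers)
            if rng.random() < config.noise_rate:
                text = text + " " + rng.choice(fillers)
            # character-level typo
            if rng.random() < config.noise_rate:
                text = _typo(text, spans, rng)
            out.append(
                SyntheticResponse(
                    response_id=f"{pid}-{qu}",
                    participant_id=pid,
                    question_id=qu,
                    text=text,
                    gold=gold,
                    template_id=tpl.template_id,
                    ne_spans=spans,
                    slot_fills=fills,
                )
            )
    return out


def generate_gold_annotations(responses: Sequence[SyntheticResponse]) -> dict[str, str]:
    """Inline-XML gold entity annotations keyed by response id, emitted at
    the known slot offsets (maximal extent, non-nested by construction)."""
    return {
        r.response_id: write_inline_xml(r.text, r.ne_spans)
        for r in responses
    }


def write_jsonl(responses: Sequence[SyntheticResponse], path: str | Path, seed: Optional[int] = None) -> None:
    """Responses in the pipeline's JSON-lines reader format; the header
    line records the generator seed."""
    with open(path, "w", encoding="utf-8") as fh:
        if seed is not None:
            fh.write(json.dumps({"_generator_seed": seed}) + "\n")
        for i, r in enumerate(responses):
            fh.write(
                json.dumps(
                    {
                        "participant_id": r.participant_id,
                        "timestamp": f"2024-01-{(i % 28) + 1:02d}T09:00:00",
                        "question_id": r.question_id,
                        "text": r.text,
                        "gold": r.gold,
                    }
                )
                + "\n"
            )


def write_gold_csv(responses: Sequence[SyntheticResponse], path: str | Path) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["response_id", "question_id", "gold"])
        for r in responses:
            w.writerow([r.response_id, r.question_id, r.gold if r.gold is not None else ""])
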