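# Methods

## Problem and pipeline

The package maps free-text answers to a 10-item open-ended knee-health
questionnaire onto structured outputs. Two question types exist. The two
open questions (Q1 current condition, Q2 current treatment) are answered
by named-entity recognition with concept normalization: the answer is the
list of recognized, normalized concept mentions. The eight remaining
questions are ordinal classification tasks on a 3-point Likert scale with
question-specific class semantics:

| Question | topic | 1 | 2 | 3 |
|---|---|---|---|---|
| Q3 | changes | worse | same | better |
| Q4 | confidence | no | reasonably | fully |
| Q5–Q7 | stiffness / pain / other symptoms | none | some | severe |
| Q8–Q9 | daily activities / work & hobbies | not at all | somewhat | a lot |
| Q10 | other comments | negative | neutral | positive |

The pipeline has two subsystems. Feature extraction runs four modules per
response — linguistic pre-processing (sentences, tokens, POS, lemmas,
dependencies), sentiment analysis, named-entity recognition and graded
lexicon lookup — and assembles their outputs into per-question feature
vectors. Classification trains one model per question and evaluates it
under stratified 10-fold cross-validation with pooled confusion matrices.

## Parsing backend

Parsing is behind an adapter interface (`ParserBackend`); the shipped
default is a deterministic rule-based backend: a regex tokenizer with
character offsets, a closed-class-dictionary + suffix POS tagger whose
open-class dictionaries cover the vocabulary of short knee-symptom
narratives, a small rule lemmatizer, and head-attachment heuristics that
produce labelled dependency trees. Copular clauses follow the classic
Stanford convention (linking verb heads the clause; subject `nsubj`,
predicate `attr`), because the negation rules below propagate through the
copula. The backend guarantees the structural contract downstream stages
rely on — offset round-trip, exactly one head per token, acyclicity — but
it is not a general-purpose parser; texts far from the questionnaire
domain will tag and attach worse than a trained parser would. Swapping in
a trained parser only requires implementing the adapter.

## Concept recognition and normalization

The full biomedical terminology the approach presumes (millions of
concepts, 133 semantic types) cannot be redistributed, so the package
bundles a mini-lexicon (~190 entries) with the identical structure:
`concept_id \t name \t semantic_type`, synonyms sharing one id. Matching
is greedy leftmost-longest over lemmas, case-insensitive; equal-length
ties break by lexicon file order; nested mentions are never emitted,
mirroring the annotation convention of maximal non-nested extents. Q1
returns condition/procedure/anatomy mentions. The treatment types for Q2
were never enumerated in the original description beyond a class count of
four, so the package uses {procedure, drug, device, exercise-activity};
this choice is a config-visible default, not canon. The bundled lexicon
deliberately includes layman synonyms (physio → physiotherapy, cardio →
cardiovascular exercises) that the original system's terminology missed.

## Negation

Only explicit syntactic negation is detected — an overt cue whose scope
is recoverable from grammatical relations. The rule inventory (the
original work shows worked figures but states no rules) is:

* **R1** a negating adverb/particle (*not, n't, never, hardly, barely*)
  attached by `advmod` marks its head;
* **R2** a negative determiner (*no, neither, none*) marks its nominal
  head;
* **R3** a marked copular/linking verb propagates to its `nsubj` subject
  and `attr` predicate — "The pain is not constant." marks both *pain*
  and *constant*;
* **R4** a marked nominal propagates to its `amod` modifiers — "no
  constant pain" cancels *constant*.

Rules can be toggled individually. Implicit/pragmatic negation (the verb
*to ease* effectively negating *pain*) is out of scope by design; the
sentiment scorer partially compensates since such verbs can carry lexicon
polarity.

## Sentiment

The scorer is pluggable (`SentimentScorer`); the default sums a graded
polarity lexicon (term → score in [−1, 1], ~90 terms) over token lemmas,
flips the sign of tokens negated by the rules above, normalizes by the
number of polar tokens hit, and labels the sentence negative/neutral/
positive with a neutral band of |score| < 0.1 (configurable). A trained
neural scorer can be substituted through the interface; none is bundled
because no suitable trained model can be shipped as data, and the
lexicon default is transparent and auditable.

## Graded lexicons and collocation induction

Severity evidence comes from aspect-keyed graded lexicons
(modifier → grade 1/2/3); six ship with the package (pain, stiffness,
symptoms, confidence, limitation, change). Grade lookup takes the maximum
grade over a headword's adjectival modifiers, immediately preceding
modifiers and copular predicates, skipping any modifier cancelled by
negation. Candidate modifiers for new lexicons are induced from any
plain-text corpus by pointwise mutual information,
PMI(c,t) = log2(N·f(c,t) / (f(c)·f(t))), counted within a ±5-token window
inside sentences with an adjective POS filter by default (base-2, window
and filter configurable; the source corpus the original work used is
licensed and is not shipped). Grading the ranked list stays manual by
design — it is small and needs no medical expertise.

## Feature schemas

Only the per-question feature *counts* of the original system were
published (Q3: 8, Q4: 8, Q5: 8, Q6: 10, Q7: 5, Q8: 14, Q9: 14), never the
feature identities. The default schemas reproduce those dimensionalities
with this package's own compositions of seven descriptor sources
(ner-count, ner-negated-count, grade-max, negation-count,
sentiment-score, one-hot sentiment-label, keyword-flag); they are
non-canonical and overridable via YAML. Multi-sentence aggregation: counts
sum over sentences, grades aggregate by maximum severity, sentiment by
mean score and majority label (ties → neutral). Q10 bypasses learned
classification: the majority sentence-polarity label is the prediction
(a per-response rule; whether the original applied it per sentence or per
response was unstated). The negation-count feature counts distinct cue
tokens, not marked tokens, so one *no* negating two words is one negation.

## Classifiers

Base learners are library-backed behind `ClassifierSpec`: naive Bayes,
complement naive Bayes, a pruned decision tree in three pruning flavours
standing in for the three tree variants of the original workbench
(cost-complexity pruning, best-first growth capped at 16 leaves, and
stronger pruning with a minimum leaf size), and a 100-tree random forest.
Numeric features are equal-width binned (5 bins) before both naive Bayes
variants: the vectors mix small counts, ordinal grades and a bounded
score that are multimodal within classes, and binning both models that
multimodality and avoids the Gaussian variance collapse that
near-constant count features otherwise cause; complement NB receives the
bins one-hot so they act as occurrence counts. The ordinal decomposition
wrapper is implemented in-repo (k−1 threshold models, composition with
clipping and renormalization, argmax with ties toward the lower class); a
threshold whose training fold is single-class degenerates to a constant
probability. Cross-validation is stratified when every class has at least
k members, otherwise plain shuffled folds with a warning; all seeds are
explicit (default 42, k = 10).

## Evaluation

Per class: P = TP/(TP+FP), R = TP/(TP+FN), F their harmonic mean, with
0/0 reported as 0 and flagged degenerate. Weighted averages weight
per-class values by actual-class support; the reported F is therefore the
support-weighted mean of per-class F, not the harmonic mean of weighted P
and R (the published per-question table is itself inconsistent with the
harmonic-mean reading). Cohen's kappa uses marginal-product expected
agreement; weighted kappa uses the disagreement-weight form
κ_w = 1 − Σw′o/Σw′e with linear agreement weights by default (quadratic
or custom available; identity weights reduce exactly to unweighted
kappa). Summary statistics use the sample (n−1) standard deviation —
required to reproduce the published cross-question dispersion — and
report percentages rounded half-up to one decimal.

## Synthetic data

The study's responses are private, so the generator emulates their form:
per-question templates follow the class semantics above (change verbs for
Q3, confidence phrases for Q4, symptom + graded modifier for Q5–Q7,
activity limitation with entity slots for Q8–Q9, polar comments for Q10),
with entity slots filled from the mini-lexicon so gold labels and gold
entity offsets hold by construction. Defaults mirror the study scale: 55
responses per question, uniform class distribution, 1–2 sentences per
response, 5% noise. The negation rate (default 0.5) sets how often a
class-1/absence response uses an explicit negation cue rather than an
absence phrasing. Noise operators: a length-preserving character typo in
a content word outside entity spans, a synonym swap within a concept, and
neutral distractor-sentence insertion (for Q10 the continuation sentences
match the comment's polarity — under majority voting a neutral filler
would make a one-polar-sentence response genuinely ambiguous, which is a
property of the voting rule, not of the data). One seeded generator
drives all randomness; a fixed seed reproduces the corpus byte for byte.

What passing tests on this corpus do and do not show: the generator
encodes exactly the signal the features are designed to capture, so
end-to-end recovery (weighted F ≥ 0.9 per question at 300
responses/question and 5% noise) demonstrates that the pipeline's stages
compose correctly and lose little signal — not that real patient language,
with its paraphrase diversity, misspellings and implicit negation, would
score comparably. The published results on real data (weighted F between
59.0 and 91.3% across questions) sit far below the synthetic ceiling for
exactly that reason.

## Problem sizes and numerical choices

The acceptance script uses 300 responses per question for recovery and
100 per question over five seeds for the noise-degradation comparison —
sizes at which the multinomial class counts are stable while the whole
script stays in the seconds range. Tie-breaks are fixed throughout
(lexicon file order for equal-length matches, lower class on probability
ties, neutral on sentiment-vote ties); cross-question summary statistics
use exact (`fsum`) summation so they are permutation-invariant; rounding
is half-up at one decimal for report formatting only, never inside
computations.

## Known limitations

The rule-based parser is domain-tuned, not general; negation handles
coordination ("neither … nor") only through the determiner rule; graded
lexicons cover single-word modifiers only; the mini-lexicon is a few
hundred entries, so real-world recall would be bounded by terminology
coverage (the same failure mode the original analysis reports for
layman's terms and rehabilitation-specific exercises); and the sentiment
default is a lexicon sum, blind to clause-level composition.
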