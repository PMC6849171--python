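# kneetext

Text mining for open-ended knee-health questionnaires.

Closed-ended patient-reported outcome measures (PROMs) such as the widely
used 42-item knee injury and osteoarthritis score are easy to score but
discard everything a patient says in their own words. An open-ended,
10-item rewrite of such a questionnaire captures far richer narratives —
at the cost of interpreting free text. `kneetext` automates that
interpretation for short (1–3 sentence) first-person answers:

* **Q1–Q2** (current condition, current treatment): dictionary-based
  named-entity recognition against a mini-lexicon with the structure of a
  large biomedical terminology (unique concept ids shared by all synonym
  names, coarse semantic types), so *swelling*, *edema* and *oedema*
  normalize to one concept and the recognized mentions **are** the answer.
* **Q3–Q10** (change, confidence, stiffness, pain, other symptoms, daily
  activities, work/hobbies, free comments): **ordinal classification** on
  a 3-point Likert scale (e.g. none < some < severe), from feature vectors
  that combine four evidence sources — concept-mention counts, explicit
  syntactic negation recovered from dependency graphs, graded severity
  lexicons (*mild* → 2, *constant* → 3, *pain-free* → 1), and sentence
  sentiment polarity.

The ordering-aware part is a binary-decomposition wrapper over any base
classifier: for k ordered classes it fits k−1 threshold models for
Pr(y > i) and composes class probabilities

```
P(1) = 1 − Pr(y>1),   P(i) = Pr(y>i−1) − Pr(y>i),   P(k) = Pr(y>k−1)
```

with negative intermediate masses clipped and renormalized. Evaluation is
10-fold cross-validation with pooled confusion matrices, per-class and
support-weighted precision/recall/F-measure, and Cohen's / weighted kappa
for agreement analysis. Because real questionnaire responses are private
clinical data, the package ships a seeded synthetic-response generator
whose templates carry gold labels and gold entity offsets by construction,
so every stage is testable offline.

## Worked example

```python
from kneetext import parse, recognize, detect_negation, load_default_resources
from kneetext.lexicon import grade_for_headword

res = load_default_resources()

doc = parse("I completely ruptured my ACL and had ACL reconstruction "
            "surgery using a hamstring graft.")
for m in recognize(doc, res.minilexicon, {"cond", "proc", "anat"}):
    print(f"{m.text!r:30} {m.semantic_type}  {m.concept_id}")
```

prints the five maximal, non-overlapping concept mentions that answer the
condition question — note both `ACL` mentions normalize to the same
concept id:

```
'completely ruptured'          cond  K0005
'ACL'                          anat  K0102
'ACL'                          anat  K0102
'reconstruction surgery'       proc  K0201
'hamstring graft'              proc  K0202
```

Negation scope comes from the dependency graph, so only the first *pain*
is negated here:

```python
sent = parse("No pain when sitting, some pain when walking upstairs.").sentences[0]
for mk in detect_negation(sent, 0):
    print("negated:", sent.tokens[mk.token_index].surface,
          "cue:", sent.tokens[mk.cue_index].surface, "rule:", mk.rule)
# negated: pain cue: No rule: R2
```

and the graded pain lexicon turns collocated modifiers into severity
evidence:

```python
grade_for_headword(parse("Intermittent pain around the joint."),
                   ["pain"], res.graded["pain"])   # -> 2  (some)
```

A full corpus-level run from the shell:

```bash
kneetext simulate --n 55 --seed 7 --noise 0.05 --out responses.jsonl
kneetext evaluate --responses responses.jsonl --out-dir reports --cv 10 --seed 42
```

writes one feature CSV per question, the Q1/Q2 concept answers, a
per-question results table (`reports/results.csv`, columns Question /
Topic / Classes / Method / Features / P % / R % / F %) and a summary with
the mean, sample standard deviation, minimum and maximum of the weighted
F-measures across questions.

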