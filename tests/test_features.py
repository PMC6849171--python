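"""Per-question feature assembly: schema dimensionalities, worked
examples, determinism and aggregation soundness."""

import pytest

from kneetext.features import (
    CLASS_SCHEMES,
    default_schemas,
    extract_features,
    predict_sentiment_class,
    scheme_for,
    vectors_to_frame,
)
from kneetext.ner import load_lexicon
from kneetext.preprocess import parse


PUBLISHED_DIMENSIONALITIES = {"Q3": 8, "Q4": 8, "Q5": 8, "Q6": 10, "Q7": 5, "Q8": 14, "Q9": 14}


class TestSchemas:
    @pytest.mark.parametrize("qid,dim", sorted(PUBLISHED_DIMENSIONALITIES.items()))
    def test_default_dimensionalities(self, schemas, qid, dim):
        assert schemas[qid].length == dim

    def test_all_schemas_positive_length(self, schemas):
        assert all(s.length > 0 for s in schemas.values())

    def test_class_schemes(self):
        assert scheme_for("Q3").class_names == ("worse", "same", "better")
        assert scheme_for("Q6").class_names == ("none", "some", "severe")
        assert scheme_for("Q8").class_names == ("not at all", "somewhat", "a lot")
        assert scheme_for("Q10").class_names == ("negative", "neutral", "positive")
        assert set(CLASS_SCHEMES) == {f"Q{i}" for i in range(3, 11)}

    def test_unknown_question_is_hard_error(self, schemas, resources):
        with pytest.raises((KeyError, ValueError)):
            extract_features("text", "Q99", schemas["Q6"], resources)


class TestExtraction:
    def test_activity_answer_counts_at_least_seven_mentions(self, schemas, resources):
        text = (
            "Not been able to carry out my normal job at work due to my injury "
            "as I am a commercial vehicle mechanic. Limited exercise and hobbies "
            "I haven't been able to play squash due to the injury and golf."
        )
        v = extract_features(text, "Q9", schemas["Q9"], resources)
        by_name = dict(zip(v.column_names, v.values))
        activity_total = (
            by_name["dora_mentions"] + by_name["ocdi_mentions"]
            + by_name["ocac_mentions"] + by_name["prog_mentions"]
        )
        assert activity_total >= 7

    def test_severe_pain_grade_and_no_negation(self, schemas, resources):
        v = extract_features(
            "Constant pain whether sitting or standing.", "Q6", schemas["Q6"], resources
        )
        by_name = dict(zip(v.column_names, v.values))
        assert by_name["grade_pain"] == 3.0
        assert by_name["negation_count"] == 0.0

    def test_fully_negated_mentions(self, schemas, resources):
        """Every symptom mention negated: negated count equals the mention
        count and no grade survives."""
        v = extract_features(
            "No pain when sitting and no pain when standing.",
            "Q6", schemas["Q6"], resources,
        )
        by_name = dict(zip(v.column_names, v.values))
        assert by_name["symptom_mentions"] == by_name["negated_symptom_mentions"] > 0
        assert by_name["grade_pain"] == 0.0

    def test_vector_length_matches_schema(self, schemas, resources):
        for q, schema in schemas.items():
            v = extract_features("Some mild pain when walking.", q, schema, resources)
            assert len(v.values) == schema.length == len(v.column_names)

    def test_extraction_deterministic(self, schemas, resources):
        text = "Occasional dull pain after swimming; no stiffness at all."
        a = extract_features(text, "Q6", schemas["Q6"], resources)
        b = extract_features(text, "Q6", schemas["Q6"], resources)
        assert a.values == b.values
        csv_a = vectors_to_frame([a]).to_csv(index=False)
        csv_b = vectors_to_frame([b]).to_csv(index=False)
        assert csv_a == csv_b

    def test_missing_aspect_lexicon_is_hard_error(self, schemas, resources):
        import dataclasses

        broken = dataclasses.replace(resources)
        broken.graded = {k: v for k, v in resources.graded.items() if k != "pain"}
        with pytest.raises(KeyError, match="pain"):
            extract_features("Mild pain.", "Q6", schemas["Q6"], broken)

    def test_merging_synonyms_never_increases_ner_count(self, schemas, resources, tmp_path):
        """Two names as distinct concepts vs the same concept: the mention
        count is unchanged (concepts collapse, spans do not)."""
        split = tmp_path / "split.tsv"
        split.write_text(
            "concept_id\tname\tsemantic_type\nA\tswelling\tsosy\nB\toedema\tsosy\n"
        )
        merged = tmp_path / "merged.tsv"
        merged.write_text(
            "concept_id\tname\tsemantic_type\nA\tswelling\tsosy\nA\toedema\tsosy\n"
        )
        import dataclasses

        text = "Swelling in the morning and oedema at night."
        counts = {}
        for name, path in [("split", split), ("merged", merged)]:
            r = dataclasses.replace(resources)
            r.minilexicon = load_lexicon(path)
            v = extract_features(text, "Q7", schemas["Q7"], r)
            counts[name] = dict(zip(v.column_names, v.values))["symptom_mentions"]
        assert counts["merged"] <= counts["split"]


class TestSentimentRoute:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("It has been an awful week and I am very unhappy.", 1),
            ("My next appointment is in two weeks.", 2),
            ("I feel great and very happy with the treatment.", 3),
        ],
    )
    def test_comments_classified_by_polarity(self, resources, text, expected):
        assert predict_sentiment_class(parse(text), resources) == expected

    def test_tie_breaks_to_neutral(self, resources):
        doc = parse("I feel great. It was awful.")
        assert predict_sentiment_class(doc, resources) == 2
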