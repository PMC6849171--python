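"""Dictionary NER: loading, greedy leftmost-longest matching, concept
normalization and the inline-XML gold format."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from kneetext.ner import (
    GoldSpan,
    answer_open_question,
    load_lexicon,
    mentions_to_gold,
    normalize,
    read_inline_xml,
    recognize,
    write_inline_xml,
)
from kneetext.preprocess import lemmatize_phrase, parse


class TestLoading:
    def test_synonyms_share_one_concept(self, tiny_lexicon):
        lex = load_lexicon(tiny_lexicon)
        assert len(lex.concept_ids) == 3
        assert len([e for e in lex.entries if e.concept_id == "C1"]) == 3

    def test_empty_file_gives_empty_lexicon(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        assert load_lexicon(p).entries == []

    def test_missing_column_is_hard_error(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("concept_id\tname\nC1\tswelling\n")
        with pytest.raises(ValueError, match="semantic_type"):
            load_lexicon(p)

    def test_extra_columns_ignored_and_duplicates_collapsed(self, tmp_path):
        p = tmp_path / "extra.tsv"
        p.write_text(
            "concept_id\tname\tsemantic_type\tcomment\n"
            "C1\tswelling\tsosy\tx\n"
            "C1\tswelling\tsosy\ty\n"
        )
        lex = load_lexicon(p)
        assert len(lex.entries) == 1


class TestRecognize:
    def test_condition_question_worked_example(self, minilex):
        doc = parse(
            "I completely ruptured my ACL and had ACL reconstruction surgery "
            "using a hamstring graft."
        )
        mentions = answer_open_question(doc, minilex, "Q1")
        assert [(m.text, m.semantic_type) for m in mentions] == [
            ("completely ruptured", "cond"),
            ("ACL", "anat"),
            ("ACL", "anat"),
            ("reconstruction surgery", "proc"),
            ("hamstring graft", "proc"),
        ]

    def test_activity_question_worked_example(self, minilex):
        doc = parse(
            "Not been able to carry out my normal job at work due to my injury "
            "as I am a commercial vehicle mechanic. Limited exercise and hobbies "
            "I haven't been able to play squash due to the injury and golf as I "
            "can't twist my knee fully yet."
        )
        mentions = recognize(doc, minilex, {"dora", "ocdi", "ocac", "prog"})
        got = [(m.text, m.semantic_type) for m in mentions]
        assert ("job", "ocdi") in got and ("work", "ocac") in got
        assert ("vehicle mechanic", "prog") in got
        assert sum(1 for _, t in got if t == "dora") >= 4
        assert len(got) >= 7

    def test_no_lexicon_names_means_no_mentions(self, minilex):
        assert recognize(parse("It was a quiet uneventful spell."), minilex) == []

    def test_type_filter_soundness(self, minilex):
        doc = parse("Swelling after physiotherapy and squats near the kneecap.")
        for types in ({"sosy"}, {"proc"}, {"anat", "exac"}):
            for m in recognize(doc, minilex, types):
                assert m.semantic_type in types

    def test_greedy_matches_brute_force_oracle(self, minilex):
        """On short sentences the greedy scan must equal an exhaustive
        enumerate-then-greedy reference."""
        texts = [
            "I completely ruptured my ACL and had reconstruction surgery.",
            "Physio and stretches for the torn meniscus and knee brace.",
            "Severe swelling and clicking when climbing stairs at work.",
            "Knee replacement then hydrotherapy, squash and golf weekly.",
        ]
        name_lemmas = {}
        for e in minilex.entries:
            name_lemmas.setdefault(lemmatize_phrase(e.name), e)
        for text in texts:
            doc = parse(text)
            got = [(m.sentence_index, m.start, m.end) for m in recognize(doc, minilex)]
            expected = []
            for si, sent in enumerate(doc.sentences):
                lemmas = [t.lemma.lower() for t in sent.tokens]
                assert len(lemmas) <= 15
                candidates = [
                    (i, j)
                    for i, j in itertools.combinations(range(len(lemmas) + 1), 2)
                    if tuple(lemmas[i:j]) in name_lemmas
                ]
                i = 0
                while i < len(lemmas):
                    starts = [c for c in candidates if c[0] == i]
                    if starts:
                        j = max(e for _, e in starts)
                        expected.append((si, i, j))
                        i = j
                    else:
                        i += 1
            assert got == expected
            # non-overlap
            for (s1, a1, b1), (s2, a2, b2) in itertools.combinations(got, 2):
                assert s1 != s2 or b1 <= a2 or b2 <= a1


class TestNormalize:
    @pytest.mark.parametrize("name", ["oedema", "edema", "OEDEMA", "swelling"])
    def test_synonyms_map_to_one_id(self, minilex, name):
        assert normalize(name, minilex) == normalize("swelling", minilex)

    def test_unknown_name_is_none(self, minilex):
        assert normalize("hamstring curls", minilex) is None

    def test_synonym_consistency_across_lexicon(self, minilex):
        """Recognizing any synonym name yields that concept's id."""
        for e in minilex.entries[:50]:
            doc = parse(e.name + ".")
            hits = [m for m in recognize(doc, minilex) if m.concept_id == e.concept_id]
            assert hits, e


class TestOpenQuestions:
    def test_layman_treatment_synonym_normalized(self, minilex):
        mentions = answer_open_question(parse("physio"), minilex, "Q2")
        assert len(mentions) == 1
        assert mentions[0].concept_id == normalize("physiotherapy", minilex)

    def test_empty_answer(self, minilex):
        assert answer_open_question(parse(""), minilex, "Q1") == []

    def test_other_questions_rejected(self, minilex):
        with pytest.raises(ValueError):
            answer_open_question(parse("x"), minilex, "Q5")


class TestInlineXml:
    def test_read_worked_annotation(self):
        text, spans = read_inline_xml(
            "I <ne1>completely ruptured</ne1> my <ne3>ACL</ne3> and had "
            "<ne2>reconstruction surgery</ne2>."
        )
        assert [s.semantic_type for s in spans] == ["cond", "anat", "proc"]
        for s in spans:
            assert text[s.char_start : s.char_end] == s.text

    def test_round_trip(self, minilex):
        doc = parse("Severe swelling after physiotherapy.")
        mentions = recognize(doc, minilex)
        gold = mentions_to_gold(mentions)
        xml = write_inline_xml(doc.text, gold)
        text2, spans2 = read_inline_xml(xml)
        assert text2 == doc.text
        assert [(s.char_start, s.char_end, s.semantic_type) for s in spans2] == [
            (s.char_start, s.char_end, s.semantic_type) for s in gold
        ]

    def test_overlap_rejected(self):
        spans = [
            GoldSpan(0, 5, "abcde", "sosy"),
            GoldSpan(3, 8, "defgh", "sosy"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            write_inline_xml("abcdefghij", spans)

    def test_nested_tags_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            read_inline_xml("<ne1>a <ne2>b</ne2></ne1>")
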