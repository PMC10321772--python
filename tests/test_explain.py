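"""Sentence segmentation, similarity strategies, the NER discount, and
passage/evidence extraction."""

import numpy as np
import pytest

from truthsearch.corpus_io import Document, JournalArticle, Topic
from truthsearch.explain import (
    ExplainConfig,
    Passage,
    SentenceScorer,
    base_similarity,
    explain_document,
    extract_evidence,
    extract_query_passages,
    read_explanations,
    segment_sentences,
    sigma_similarity,
    write_explanations,
)
from truthsearch.representation import DictionaryNER, cosine


@pytest.fixture
def ner():
    return DictionaryNER(
        medications=["vitamin c", "vitamin d", "zinc"],
        diseases=["covid-19", "scurvy"],
    )


class TestSegmentSentences:
    def test_two_sentences_with_spans(self):
        text = "A is true. B is false."
        parts = segment_sentences(text, "d")
        assert [p.text for p in parts] == ["A is true.", "B is false."]
        for p in parts:
            assert text[p.char_span[0] : p.char_span[1]] == p.text
        assert parts[0].sent_index == 0 and parts[1].sent_index == 1

    def test_no_terminal_punctuation_single_passage(self):
        text = "no punctuation at all here"
        (p,) = segment_sentences(text)
        assert p.text == text
        assert p.char_span == (0, len(text))

    def test_abbreviation_not_a_boundary(self):
        parts = segment_sentences("Dosage, e.g. 50 mg, is low. Next claim.")
        assert len(parts) == 2
        assert parts[0].text.startswith("Dosage")

    def test_empty_and_whitespace_inputs(self):
        assert segment_sentences("") == []
        assert segment_sentences("   \n ") == []

    def test_question_and_exclamation_boundaries(self):
        parts = segment_sentences("Really? Yes! Fine.")
        assert [p.text for p in parts] == ["Really?", "Yes!", "Fine."]

    def test_reconstruction_oracle_on_synthetic_docs(self, synth_corpus):
        for doc in synth_corpus.documents[:50]:
            parts = segment_sentences(doc.text, doc.doc_id)
            # spans ordered, non-overlapping, gaps whitespace-only
            prev_end = 0
            rebuilt = []
            for p in parts:
                start, end = p.char_span
                assert start >= prev_end
                assert doc.text[prev_end:start].strip() == ""
                assert doc.text[start:end] == p.text
                rebuilt.append(p.text)
                prev_end = end
            assert doc.text[prev_end:].strip() == ""
            assert "".join(rebuilt).replace(" ", "") == doc.text.replace(
                " ", ""
            )


class TestBaseSimilarity:
    def test_tfidf_identity(self):
        scorer = SentenceScorer(
            ["zinc treats colds.", "aspirin treats pain."], "tfidf"
        )
        q = "zinc treats colds."
        assert base_similarity(q, q, "tfidf", scorer) == pytest.approx(1.0)

    def test_bm25_absent_term_zero(self):
        scorer = SentenceScorer(
            ["zinc treats colds.", "aspirin treats pain."], "bm25"
        )
        assert base_similarity(
            "gardening", "zinc treats colds.", "bm25", scorer
        ) == 0.0

    def test_embedding_matches_cosine_oracle(self, backend):
        sentences = ["zinc treats colds.", "aspirin treats pain."]
        scorer = SentenceScorer(sentences, "embedding", backend)
        q = "does zinc treat colds?"
        for s in sentences:
            expected = cosine(backend.embed(q), backend.embed(s))
            assert base_similarity(q, s, "embedding", scorer) == (
                pytest.approx(expected, abs=1e-9)
            )

    def test_strategy_context_mismatch_rejected(self, backend):
        scorer = SentenceScorer(["a."], "embedding", backend)
        with pytest.raises(ValueError):
            base_similarity("q", "a.", "tfidf", scorer)

    def test_bm25_unknown_sentence_rejected(self):
        scorer = SentenceScorer(["known sentence."], "bm25")
        with pytest.raises(KeyError):
            scorer.sim("query", "never seen before.")


class TestSigmaSimilarity:
    def _scorer(self, backend):
        return SentenceScorer(
            ["vitamin c cures scurvy.", "vitamin d cures scurvy."],
            "embedding",
            backend,
        )

    def test_match_keeps_sim(self, backend, ner):
        cfg = ExplainConfig(use_ner=True, w_d=0.5)
        scorer = self._scorer(backend)
        q = "can vitamin c cure scurvy?"
        s = "vitamin c cures scurvy."
        assert sigma_similarity(q, s, cfg, ner, scorer) == pytest.approx(
            scorer.sim(q, s)
        )

    def test_mismatch_discounts_by_wd(self, backend, ner):
        cfg = ExplainConfig(use_ner=True, w_d=0.5)
        scorer = self._scorer(backend)
        q = "can vitamin c cure scurvy?"
        s = "vitamin d cures scurvy."
        assert sigma_similarity(q, s, cfg, ner, scorer) == pytest.approx(
            0.5 * scorer.sim(q, s)
        )

    def test_wd_one_is_identity(self, backend, ner):
        cfg = ExplainConfig(use_ner=True, w_d=1.0)
        scorer = self._scorer(backend)
        q = "can vitamin c cure scurvy?"
        for s in scorer.sentences:
            assert sigma_similarity(q, s, cfg, ner, scorer) == pytest.approx(
                scorer.sim(q, s)
            )

    def test_ner_disabled_is_identity(self, backend):
        cfg = ExplainConfig(use_ner=False, w_d=0.1)
        scorer = self._scorer(backend)
        q = "can vitamin c cure scurvy?"
        for s in scorer.sentences:
            assert sigma_similarity(q, s, cfg, None, scorer) == pytest.approx(
                scorer.sim(q, s)
            )


class TestExtractQueryPassages:
    def test_vocabulary_overlap_sentence_ranks_first(self, backend):
        doc = Document(
            "d1",
            "Gardening is a popular hobby. Zinc lozenges shorten colds. "
            "Painting relaxes the mind.",
        )
        cfg = ExplainConfig(strategy="embedding", use_ner=False, n_passages=3)
        passages = extract_query_passages(
            "do zinc lozenges shorten colds?", doc, cfg, backends=backend
        )
        assert passages[0].text == "Zinc lozenges shorten colds."
        assert passages[0].score > passages[1].score

    def test_p_exceeding_sentence_count_returns_all(self, backend):
        doc = Document("d1", "One. Two.")
        cfg = ExplainConfig(strategy="embedding", use_ner=False, n_passages=9)
        assert len(
            extract_query_passages("one", doc, cfg, backends=backend)
        ) == 2

    def test_entity_mismatch_demotes_equal_similarity(self, backend, ner):
        # Both sentences identical up to the entity; NER breaks the tie.
        doc = Document(
            "d1",
            "vitamin c prevents scurvy at sea. "
            "vitamin d prevents scurvy at sea.",
        )
        cfg = ExplainConfig(strategy="embedding", use_ner=True, w_d=0.5,
                            n_passages=2)
        passages = extract_query_passages(
            "does vitamin c prevent scurvy?", doc, cfg, ner, backend
        )
        assert "vitamin c" in passages[0].text
        assert passages[0].score > passages[1].score

    @pytest.mark.parametrize("strategy", ["tfidf", "bm25", "embedding"])
    def test_all_strategies_run(self, strategy, backend, ner):
        doc = Document("d1", "Zinc helps colds. Unrelated filler text here.")
        cfg = ExplainConfig(strategy=strategy, use_ner=True, n_passages=2)
        passages = extract_query_passages(
            "does zinc help colds?", doc, cfg, ner, backend
        )
        assert passages and passages[0].text == "Zinc helps colds."

    def test_sentence_order_permutation_invariance(self, backend):
        cfg = ExplainConfig(strategy="embedding", use_ner=False, n_passages=1)
        d1 = Document("a", "Filler sentence here. Zinc shortens colds.")
        d2 = Document("b", "Zinc shortens colds. Filler sentence here.")
        q = "does zinc shorten colds?"
        p1 = extract_query_passages(q, d1, cfg, backends=backend)
        p2 = extract_query_passages(q, d2, cfg, backends=backend)
        assert p1[0].text == p2[0].text
        assert p1[0].score == pytest.approx(p2[0].score)


class TestExtractEvidence:
    def _passage(self, text):
        return Passage("d1", 0, text, (0, len(text)), 0.9)

    def test_verbatim_copy_is_top_evidence(self, backend):
        passage = self._passage("zinc shortens colds.")
        journals = [
            JournalArticle(
                "j1", "unrelated opening. zinc shortens colds. more filler."
            )
        ]
        cfg = ExplainConfig(strategy="embedding", use_ner=False, n_evidence=5)
        items = extract_evidence(passage, journals, cfg, backends=backend)
        assert items[0].text == "zinc shortens colds."
        assert items[0].score == pytest.approx(1.0)

    def test_truncation_to_available_sentences(self, backend):
        passage = self._passage("zinc shortens colds.")
        journals = [JournalArticle("j1", "One. Two. Three.")]
        cfg = ExplainConfig(strategy="embedding", use_ner=False, n_evidence=5)
        assert len(
            extract_evidence(passage, journals, cfg, backends=backend)
        ) == 3

    def test_entity_swapped_evidence_demoted(self, backend, ner):
        passage = self._passage("vitamin c prevents scurvy at sea.")
        journals = [
            JournalArticle(
                "j1",
                "vitamin d prevents scurvy at sea. "
                "vitamin c prevents scurvy at sea.",
            )
        ]
        cfg = ExplainConfig(strategy="embedding", use_ner=True, w_d=0.5,
                            n_evidence=2)
        items = extract_evidence(passage, journals, cfg, ner, backend)
        assert "vitamin c" in items[0].text
        swapped_base = cosine(
            backend.embed(passage.text), backend.embed(items[1].text)
        )
        assert items[1].score == pytest.approx(0.5 * swapped_base)

    def test_no_journals_empty_list(self, backend):
        cfg = ExplainConfig(strategy="embedding", use_ner=False)
        assert extract_evidence(
            self._passage("x."), [], cfg, backends=backend
        ) == []


class TestExplainDocument:
    @pytest.fixture
    def world(self):
        topic = Topic("t1", "zinc colds", "does zinc shorten colds?",
                      "yes", "n")
        doc = Document(
            "d1",
            "Zinc shortens colds. Zinc is a mineral. People like soup. "
            "Walking is healthy. Reading calms nerves. Soup is warm.",
        )
        journals = [
            JournalArticle(
                "j1",
                "Zinc shortens colds. Trials support zinc supplements. "
                "Cohorts were followed monthly.",
            )
        ]
        return topic, doc, journals

    def test_shape_contract(self, world, backend):
        topic, doc, journals = world
        cfg = ExplainConfig(strategy="embedding", use_ner=False,
                            n_passages=5, n_evidence=5)
        ex = explain_document(topic, doc, journals, cfg, backends=backend)
        assert len(ex.passages) == 5
        assert len(ex.evidence) == 5
        assert all(len(ev) <= 5 for ev in ex.evidence)

    def test_json_round_trip(self, world, backend, tmp_path):
        topic, doc, journals = world
        cfg = ExplainConfig(strategy="embedding", use_ner=False,
                            n_passages=3, n_evidence=2)
        ex = explain_document(topic, doc, journals, cfg, backends=backend)
        path = tmp_path / "explanations.jsonl"
        write_explanations([ex], path)
        (back,) = read_explanations(path)
        assert back == ex

    def test_deterministic(self, world, backend):
        topic, doc, journals = world
        cfg = ExplainConfig(strategy="embedding", use_ner=False)
        a = explain_document(topic, doc, journals, cfg, backends=backend)
        b = explain_document(topic, doc, journals, cfg, backends=backend)
        assert a == b


class TestNerOffEquivalence:
    def test_disabling_ner_equals_strategy_only_ranking(self, backend, ner):
        """use_ner=False must reproduce the raw-similarity ranking, and so
        must w_d=1 (the discount becomes a no-op)."""
        doc = Document(
            "d1",
            "vitamin c prevents scurvy. vitamin d also matters. "
            "sailors ate citrus. gardening is fun.",
        )
        q = "does vitamin c prevent scurvy?"
        off = ExplainConfig(strategy="embedding", use_ner=False, n_passages=4)
        wd1 = ExplainConfig(strategy="embedding", use_ner=True, w_d=1.0,
                            n_passages=4)
        p_off = extract_query_passages(q, doc, off, backends=backend)
        p_wd1 = extract_query_passages(q, doc, wd1, ner, backend)
        assert [p.text for p in p_off] == [p.text for p in p_wd1]
        assert [p.score for p in p_off] == pytest.approx(
            [p.score for p in p_wd1]
        )


class TestExplainConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"strategy": "magic"},
            {"w_d": 1.5},
            {"w_d": -0.1},
            {"n_passages": 0},
            {"n_evidence": 0},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ExplainConfig(**kwargs)
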