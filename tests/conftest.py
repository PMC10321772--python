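"""Shared fixtures: tiny hand-made corpora and the seed-pinned synthetic
benchmark used by the mechanism-recovery and determinism tests."""

from __future__ import annotations

import pytest

from truthsearch.config import RunConfig
from truthsearch.corpus_io import Document, JournalArticle, Topic
from truthsearch.representation import DictionaryNER, HashEmbeddingBackend
from truthsearch.synthetic import SynthConfig, generate_corpus

PINNED_SEED = 7


@pytest.fixture(scope="session")
def synth_corpus():
    """The separable synthetic benchmark: 8 topics x 40 docs, entity-swap
    misinformation, half truthful."""
    return generate_corpus(SynthConfig(seed=PINNED_SEED))


@pytest.fixture(scope="session")
def synth_ner(synth_corpus):
    return DictionaryNER(synth_corpus.medications, synth_corpus.diseases)


@pytest.fixture(scope="session")
def run_config():
    return RunConfig(seed=PINNED_SEED)


@pytest.fixture
def backend():
    return HashEmbeddingBackend(dim=512, seed=0)


@pytest.fixture
def tiny_docs():
    """Four documents with transparent term statistics."""
    return [
        Document("d1", "aspirin reduces fever in adults"),
        Document("d2", "aspirin and ibuprofen reduce inflammation"),
        Document("d3", "sleep improves recovery"),
        Document("d4", "fever fever fever everywhere"),
    ]


@pytest.fixture
def tiny_journals():
    return [
        JournalArticle("j1", "aspirin reduces fever according to trials."),
        JournalArticle("j2", "sleep quality correlates with recovery speed."),
    ]


@pytest.fixture
def tiny_topic():
    return Topic(
        topic_id="t1",
        title="aspirin fever",
        description="does aspirin reduce fever?",
        answer="yes",
        narrative="documents about aspirin and fever.",
    )
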