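"""Sentence-level explanations: query-relevant passages and journal evidence.

For every retrieved document the explainer extracts the sentences most
similar to the query (*query-relevant passages*), then, for each passage,
the most similar sentences from the journal articles retrieved for the
same query (*passage-based evidence*).  Three interchangeable similarity
strategies score a (query, sentence) pair:

``tfidf``
    cosine of TF-IDF vectors, with idf statistics fitted on the sentence
    population being searched (the document's sentences for passages, the
    journal sentences for evidence);
``bm25``
    Okapi BM25 treating each sentence as a tiny document;
``embedding``
    cosine of embedding-backend vectors.

Every strategy can be sharpened with named-entity agreement: when the
medication/disease profiles of the query and the sentence disagree, the
similarity is multiplied by a discount weight ``w_d`` in [0, 1]::

    sigma(q, s) = sim(q, s)         if the entity profiles correspond
                = w_d * sim(q, s)   otherwise

so a sentence about "vitamin d" cannot outrank an equally similar
sentence about "vitamin c" for a vitamin-c query.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from sklearn.feature_extraction.text import TfidfVectorizer

from .corpus_io import Document, JournalArticle, Topic
from .representation import (
    EmbeddingBackend,
    NERBackend,
    cosine,
    ensemble_similarity,
    entities_match,
)
from .retrieval import BM25Params, bm25_score, build_index, tokenize

__all__ = [
    "Passage",
    "EvidenceItem",
    "ExplainConfig",
    "Explanation",
    "segment_sentences",
    "SentenceScorer",
    "base_similarity",
    "sigma_similarity",
    "extract_query_passages",
    "extract_evidence",
    "explain_document",
    "write_explanations",
    "read_explanations",
]

logger = logging.getLogger(__name__)

# Common abbreviations after which a period does not end a sentence.
_ABBREVIATIONS = frozenset(
    {
        "e.g",
        "i.e",
        "etc",
        "vs",
        "cf",
        "dr",
        "mr",
        "mrs",
        "ms",
        "prof",
        "fig",
        "no",
        "al",
        "st",
        "approx",
    }
)

_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s|$)")
_LAST_WORD_RE = re.compile(r"([A-Za-z][A-Za-z.]*)$")


@dataclass(frozen=True)
class Passage:
    """One sentence of a document with its query similarity.

    ``char_span`` is a 0-based half-open offset pair into the source text;
    ``text`` always equals the source slice at that span.
    """

    doc_id: str
    sent_index: int
    text: str
    char_span: tuple[int, int]
    score: float = 0.0


@dataclass(frozen=True)
class EvidenceItem:
    """One journal sentence supporting a passage, with its sigma score."""

    journal_id: str
    sent_index: int
    text: str
    score: float


@dataclass(frozen=True)
class ExplainConfig:
    """Strategy and NER-discount settings for explanation extraction.

    ``n_passages`` (P) and ``n_evidence`` (E) cap the per-document passage
    list and the per-passage evidence list; ``w_d`` is the similarity
    discount applied on an entity mismatch (1.0 disables the penalty
    without disabling extraction).
    """

    strategy: str = "embedding"
    use_ner: bool = True
    w_d: float = 0.5
    n_passages: int = 5
    n_evidence: int = 5

    def __post_init__(self) -> None:
        if self.strategy not in ("tfidf", "bm25", "embedding"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if not 0.0 <= self.w_d <= 1.0:
            raise ValueError(f"w_d must lie in [0, 1], got {self.w_d}")
        if self.n_passages < 1 or self.n_evidence < 1:
            raise ValueError("n_passages and n_evidence must be >= 1")


def segment_sentences(text: str, doc_id: str = "") -> list[Passage]:
    """Deterministic rule-based sentence segmentation with char spans.

    Splits after runs of terminal punctuation followed by whitespace,
    except when the preceding word is a known abbreviation.  Text without
    terminal punctuation yields a single sentence.  Spans are ordered,
    non-overlapping, and separated only by whitespace, so the source text
    is reconstructible from the passages.
    """
    passages: list[Passage] = []
    n = len(text)
    start = 0
    while start < n and text[start].isspace():
        start += 1
    if start >= n:
        return []
    cut_points: list[int] = []
    for match in _BOUNDARY_RE.finditer(text):
        before = text[: match.start()]
        word = _LAST_WORD_RE.search(before)
        if word and word.group(1).rstrip(".").lower() in _ABBREVIATIONS:
            continue
        cut_points.append(match.end())
    cut_points.append(n)
    sent_index = 0
    for cut in cut_points:
        if cut <= start:
            continue
        end = cut
        while end > start and text[end - 1].isspace():
            end -= 1
        if end > start:
            passages.append(
                Passage(
                    doc_id=doc_id,
                    sent_index=sent_index,
                    text=text[start:end],
                    char_span=(start, end),
                )
            )
            sent_index += 1
        start = cut
        while start < n and text[start].isspace():
            start += 1
    return passages


class SentenceScorer:
    """Strategy-specific similarity over a fixed sentence population.

    The population defines the collection statistics: the TF-IDF
    vocabulary/idf table and the BM25 index are fitted on it, so the
    same pair of texts may score differently inside different documents —
    deliberately, since relevance is relative to the searched collection.
    """

    def __init__(
        self,
        sentences: Sequence[str],
        strategy: str,
        backends: Sequence[EmbeddingBackend] | EmbeddingBackend | None = None,
        bm25_params: BM25Params = BM25Params(),
    ) -> None:
        if strategy not in ("tfidf", "bm25", "embedding"):
            raise ValueError(f"unknown strategy {strategy!r}")
        self.strategy = strategy
        self.sentences = list(sentences)
        self._bm25_params = bm25_params
        if strategy == "embedding":
            if backends is None:
                raise ValueError("embedding strategy requires a backend")
            self.backends = (
                [backends]
                if not isinstance(backends, (list, tuple))
                else list(backends)
            )
        elif strategy == "tfidf":
            tokenized_any = any(tokenize(s) for s in self.sentences)
            if tokenized_any:
                self._vectorizer = TfidfVectorizer(
                    analyzer=tokenize, lowercase=False
                )
                self._vectorizer.fit(self.sentences)
            else:
                self._vectorizer = None
        elif strategy == "bm25":
            records = [
                _SentenceRecord(f"s{i}", s) for i, s in enumerate(self.sentences)
            ]
            self._sentence_ids = {}
            for r in records:
                self._sentence_ids.setdefault(r.text, r.doc_id)
            self._index = build_index(records) if records else None

    def sim(self, query: str, sentence: str) -> float:
        """Raw (undiscounted) similarity of a query/sentence pair."""
        if self.strategy == "embedding":
            return ensemble_similarity(self.backends, query, sentence)
        if self.strategy == "tfidf":
            if self._vectorizer is None:
                return 0.0
            mat = self._vectorizer.transform([query, sentence])
            q, s = mat[0].toarray()[0], mat[1].toarray()[0]
            if not q.any() or not s.any():
                return 0.0
            return cosine(q, s)
        sid = self._sentence_ids.get(sentence)
        if sid is None:
            raise KeyError(
                "bm25 strategy can only score sentences from its population"
            )
        return bm25_score(self._index, query, sid, self._bm25_params)


@dataclass(frozen=True)
class _SentenceRecord:
    doc_id: str
    text: str


def base_similarity(
    query: str, sentence: str, strategy: str, context: SentenceScorer
) -> float:
    """Strategy similarity via a prepared :class:`SentenceScorer`."""
    if strategy != context.strategy:
        raise ValueError(
            f"context was built for {context.strategy!r}, not {strategy!r}"
        )
    return context.sim(query, sentence)


def sigma_similarity(
    query: str,
    sentence: str,
    cfg: ExplainConfig,
    ner: NERBackend | None,
    context: SentenceScorer,
) -> float:
    """NER-discounted similarity: ``sim`` on entity agreement, else
    ``w_d * sim``."""
    sim = context.sim(query, sentence)
    if not cfg.use_ner:
        return sim
    if ner is None:
        raise ValueError("use_ner=True requires an NER backend")
    if entities_match(ner.extract(query), ner.extract(sentence)):
        return sim
    return cfg.w_d * sim


def extract_query_passages(
    query: str,
    doc: Document,
    cfg: ExplainConfig,
    ner: NERBackend | None = None,
    backends=None,
    bm25_params: BM25Params = BM25Params(),
) -> list[Passage]:
    """Top-P sentences of a document by sigma similarity to the query.

    Ties are broken by source order (ascending sentence index), which
    keeps rankings reproducible and permutation-invariant.
    """
    sentences = segment_sentences(doc.text, doc.doc_id)
    if not sentences:
        logger.warning("document %s has no sentences", doc.doc_id)
        return []
    scorer = SentenceScorer(
        [p.text for p in sentences], cfg.strategy, backends, bm25_params
    )
    scored = [
        Passage(
            p.doc_id,
            p.sent_index,
            p.text,
            p.char_span,
            sigma_similarity(query, p.text, cfg, ner, scorer),
        )
        for p in sentences
    ]
    scored.sort(key=lambda p: (-p.score, p.sent_index))
    return scored[: cfg.n_passages]


def extract_evidence(
    passage: Passage,
    journal_articles: Sequence[JournalArticle],
    cfg: ExplainConfig,
    ner: NERBackend | None = None,
    backends=None,
    bm25_params: BM25Params = BM25Params(),
) -> list[EvidenceItem]:
    """Top-E journal sentences by sigma similarity to a passage.

    The passage text plays the query role; the journal articles must be
    the (rank-ordered) ones retrieved for the topic.  Ties are broken by
    journal rank, then sentence index.
    """
    pool: list[tuple[int, str, int, str]] = []
    for journal_rank, article in enumerate(journal_articles):
        for sent in segment_sentences(article.text, article.journal_id):
            pool.append(
                (journal_rank, article.journal_id, sent.sent_index, sent.text)
            )
    if not pool:
        logger.warning(
            "no journal sentences available for passage of %s", passage.doc_id
        )
        return []
    scorer = SentenceScorer(
        [text for *_, text in pool], cfg.strategy, backends, bm25_params
    )
    scored = [
        (
            sigma_similarity(passage.text, text, cfg, ner, scorer),
            journal_rank,
            sent_index,
            journal_id,
            text,
        )
        for journal_rank, journal_id, sent_index, text in pool
    ]
    scored.sort(key=lambda row: (-row[0], row[1], row[2]))
    return [
        EvidenceItem(journal_id, sent_index, text, score)
        for score, _rank, sent_index, journal_id, text in scored[
            : cfg.n_evidence
        ]
    ]


@dataclass(frozen=True)
class Explanation:
    """Per-document explanation: top passages, each with its evidence."""

    topic_id: str
    doc_id: str
    passages: tuple[Passage, ...]
    evidence: tuple[tuple[EvidenceItem, ...], ...]  # parallel to passages


def explain_document(
    topic: Topic,
    doc: Document,
    journal_articles: Sequence[JournalArticle],
    cfg: ExplainConfig,
    ner: NERBackend | None = None,
    backends=None,
    bm25_params: BM25Params = BM25Params(),
) -> Explanation:
    """Extract the top-P passages of a retrieved document and, for each,
    its top-E journal evidence sentences."""
    passages = extract_query_passages(
        topic.description, doc, cfg, ner, backends, bm25_params
    )
    evidence = tuple(
        tuple(
            extract_evidence(p, journal_articles, cfg, ner, backends, bm25_params)
        )
        for p in passages
    )
    return Explanation(topic.topic_id, doc.doc_id, tuple(passages), evidence)


def write_explanations(
    explanations: Iterable[Explanation], path: str | Path
) -> None:
    """Serialize explanations as JSON-lines."""
    with open(path, "w", encoding="utf-8") as fh:
        for ex in explanations:
            obj = {
                "topic": ex.topic_id,
                "doc": ex.doc_id,
                "passages": [
                    {
                        "text": p.text,
                        "span": list(p.char_span),
                        "sent_index": p.sent_index,
                        "score": p.score,
                        "evidence": [
                            {
                                "journal": e.journal_id,
                                "sent_index": e.sent_index,
                                "text": e.text,
                                "score": e.score,
                            }
                            for e in ev
                        ],
                    }
                    for p, ev in zip(ex.passages, ex.evidence)
                ],
            }
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def read_explanations(path: str | Path) -> list[Explanation]:
    """Read JSON-lines explanations (inverse of :func:`write_explanations`)."""
    out: list[Explanation] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            passages = []
            evidence = []
            for p in obj["passages"]:
                passages.append(
                    Passage(
                        doc_id=obj["doc"],
                        sent_index=p["sent_index"],
                        text=p["text"],
                        char_span=tuple(p["span"]),
                        score=p["score"],
                    )
                )
                evidence.append(
                    tuple(
                        EvidenceItem(
                            e["journal"], e["sent_index"], e["text"], e["score"]
                        )
                        for e in p["evidence"]
                    )
                )
            out.append(
                Explanation(
                    obj["topic"], obj["doc"], tuple(passages), tuple(evidence)
                )
            )
    return out
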