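"""Truthfulness scoring against journal evidence and RSV rank fusion.

A query retrieves two lists by BM25: candidate documents from the open
document collection and articles from a trusted journal corpus.  Each
document's *information truthfulness score* is a rank-weighted sum of its
cosine similarities to the retrieved journal articles::

    its(q, d) = sum_i  w_i * cos(d, j_i),   sum_i w_i = 1,  w_i >= w_{i+1}

so agreement with the top-ranked evidence counts most.  The final
retrieval status value linearly fuses topicality and truthfulness::

    RSV(q, d) = w_trs * BM25(q, d) + w_its * its(q, d)

Because raw BM25 is unbounded while ``its`` lies in [-1, 1], topicality
is min-max normalized within the retrieved list by default before fusion
(``topicality_normalization="none"`` reproduces the literal combination).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Document, JournalArticle, Topic
from .representation import EmbeddingBackend, cosine
from .retrieval import BM25Params, InvertedIndex, retrieve

__all__ = [
    "RankWeights",
    "FusionConfig",
    "ScoredDoc",
    "rank_weights",
    "truthfulness_score",
    "fuse_rsv",
    "rank_documents",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankWeights:
    """Normalized, non-increasing weights over the top-k journal articles."""

    k: int
    w: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if len(self.w) != self.k:
            raise ValueError(f"expected {self.k} weights, got {len(self.w)}")
        if any(wi < 0 for wi in self.w):
            raise ValueError("weights must be non-negative")
        if abs(sum(self.w) - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {sum(self.w)}")
        if any(a < b - 1e-12 for a, b in zip(self.w, self.w[1:])):
            raise ValueError("weights must be non-increasing in rank")


@dataclass(frozen=True)
class FusionConfig:
    """Linear-fusion weights and the topicality normalization switch."""

    w_trs: float = 0.5
    w_its: float = 0.5
    topicality_normalization: str = "minmax"

    def __post_init__(self) -> None:
        for name, value in (("w_trs", self.w_trs), ("w_its", self.w_its)):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.topicality_normalization not in ("minmax", "none"):
            raise ValueError(
                "topicality_normalization must be 'minmax' or 'none', "
                f"got {self.topicality_normalization!r}"
            )


@dataclass(frozen=True)
class ScoredDoc:
    """One ranked result: topicality, truthfulness, fused RSV, and rank."""

    doc_id: str
    topicality: float
    truthfulness: float
    rsv: float
    rank: int


def rank_weights(k: int, scheme: str = "reciprocal") -> RankWeights:
    """Build the rank-weight vector for the top-k journal articles.

    ``reciprocal``: w_i proportional to 1/i (emphasizes top evidence);
    ``linear``: w_i proportional to k - i + 1; ``uniform``: 1/k each.
    All schemes satisfy the sum-to-one and non-increasing constraints.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if scheme == "reciprocal":
        raw = [1.0 / i for i in range(1, k + 1)]
    elif scheme == "linear":
        raw = [float(k - i + 1) for i in range(1, k + 1)]
    elif scheme == "uniform":
        raw = [1.0] * k
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    total = sum(raw)
    return RankWeights(k=k, w=tuple(x / total for x in raw))


def truthfulness_score(
    doc_vector: np.ndarray,
    journal_vectors: Sequence[np.ndarray],
    weights: RankWeights,
) -> float:
    """Rank-weighted sum of cosines between a document and the journal
    articles retrieved for the same query; lies in [-1, 1]."""
    if len(journal_vectors) != weights.k:
        raise ValueError(
            f"got {len(journal_vectors)} journal vectors for k={weights.k}"
        )
    return float(
        sum(
            wi * cosine(doc_vector, jv)
            for wi, jv in zip(weights.w, journal_vectors)
        )
    )


def fuse_rsv(topicality: float, its: float, cfg: FusionConfig) -> float:
    """Linear fusion of topicality and truthfulness into the RSV."""
    return cfg.w_trs * topicality + cfg.w_its * its


def _minmax(scores: Sequence[float]) -> list[float]:
    lo, hi = min(scores), max(scores)
    if hi == lo:
        # All retrieved documents tie on topicality; they are maximally
        # topical relative to this list, so map to 1.0.
        return [1.0] * len(scores)
    return [(s - lo) / (hi - lo) for s in scores]


def rank_documents(
    topic: Topic,
    doc_index: InvertedIndex,
    journal_index: InvertedIndex,
    doc_corpus: Mapping[str, Document],
    journal_corpus: Mapping[str, JournalArticle],
    backend: EmbeddingBackend,
    n_docs: int = 20,
    n_journals: int = 1,
    weights_scheme: str = "reciprocal",
    fusion: FusionConfig = FusionConfig(),
    params: BM25Params = BM25Params(),
) -> list[ScoredDoc]:
    """End-to-end ranking of one topic.

    The topic description (the question form) is the query.  Steps: BM25
    over the document index (top ``n_docs``), BM25 over the journal index
    (top ``n_journals``), whole-text embedding of both sides, truthfulness
    per the rank-weighted cosine sum, then linear fusion; output sorted by
    descending RSV with ties broken by ascending doc id.  If no journal
    article is retrieved the truthfulness of every document is 0 and a
    warning is logged.
    """
    if n_docs < 1 or n_journals < 1:
        raise ValueError("n_docs and n_journals must be >= 1")
    query = topic.description
    doc_hits = retrieve(doc_index, query, n_docs, params)
    if not doc_hits:
        return []
    journal_hits = retrieve(journal_index, query, n_journals, params)

    topicalities = [score for _, score in doc_hits]
    if fusion.topicality_normalization == "minmax":
        topicalities = _minmax(topicalities)

    if journal_hits:
        weights = rank_weights(len(journal_hits), weights_scheme)
        journal_vectors = [
            backend.embed(journal_corpus[jid].text) for jid, _ in journal_hits
        ]
    else:
        logger.warning(
            "topic %s: no journal article retrieved; truthfulness set to 0",
            topic.topic_id,
        )
        weights = None
        journal_vectors = []

    results = []
    for (doc_id, _), topical in zip(doc_hits, topicalities):
        if journal_vectors:
            doc_vec = backend.embed(doc_corpus[doc_id].text)
            its = truthfulness_score(doc_vec, journal_vectors, weights)
        else:
            its = 0.0
        rsv = fuse_rsv(topical, its, fusion)
        results.append((doc_id, topical, its, rsv))
    results.sort(key=lambda r: (-r[3], r[0]))
    return [
        ScoredDoc(doc_id, topical, its, rsv, rank)
        for rank, (doc_id, topical, its, rsv) in enumerate(results, start=1)
    ]
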