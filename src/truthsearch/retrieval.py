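"""Tokenization, inverted index, and Okapi BM25 ranked retrieval.

The topicality score of a document *d* for a query *q* is the standard
Okapi BM25 sum over query terms present in the document::

    BM25(q, d) = sum_t  idf(t) * tf(t,d) * (k1 + 1)
                          / (tf(t,d) + k1 * (1 - b + b * l_d / L))

    idf(t) = ln( (N - df(t) + 0.5) / (df(t) + 0.5) )

with *N* the collection size, ``df`` the document frequency, ``tf`` the
within-document term frequency, ``l_d`` the document length in tokens and
*L* the mean document length.  Natural logarithm throughout; the raw idf
is used without clamping, so terms occurring in more than half the
collection contribute negatively — documented behaviour, reproducible.

The index is an ordinary in-memory hash-map inverted index, small enough
for the desk-scale corpora this package targets, and persists to a single
JSON file for CLI reuse.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "tokenize",
    "BM25Params",
    "InvertedIndex",
    "build_index",
    "bm25_score",
    "retrieve",
]

# Lowercased alphanumeric runs; internal hyphens are kept so terms such as
# "covid-19" survive as single tokens.
_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")


def tokenize(text: str, stopwords: frozenset[str] | None = None) -> list[str]:
    """Lowercase alphanumeric tokenization with internal hyphens kept.

    Deterministic; punctuation is stripped and empty input yields an empty
    list.  No stopwords are removed unless a list is supplied.
    """
    tokens = _TOKEN_RE.findall(text.lower())
    if stopwords:
        tokens = [t for t in tokens if t not in stopwords]
    return tokens


@dataclass(frozen=True)
class BM25Params:
    """Okapi BM25 free parameters.

    ``k1 > 0`` scales term-frequency saturation; ``b`` in [0, 1] sets the
    strength of document-length normalization (``b = 0`` disables it).
    Defaults follow the common Okapi convention.
    """

    k1: float = 1.2
    b: float = 0.75

    def __post_init__(self) -> None:
        if not self.k1 > 0:
            raise ValueError(f"k1 must be positive, got {self.k1}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must lie in [0, 1], got {self.b}")


@dataclass
class InvertedIndex:
    """In-memory inverted index holding the statistics BM25 needs."""

    N: int
    df: dict[str, int]
    postings: dict[str, dict[str, int]]  # term -> {doc_id: tf}
    doc_len: dict[str, int]
    avg_len: float
    doc_ids: list[str] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Persist to a single JSON file (terms, postings, lengths)."""
        payload = {
            "N": self.N,
            "df": self.df,
            "postings": self.postings,
            "doc_len": self.doc_len,
            "avg_len": self.avg_len,
            "doc_ids": self.doc_ids,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            N=payload["N"],
            df=payload["df"],
            postings=payload["postings"],
            doc_len=payload["doc_len"],
            avg_len=payload["avg_len"],
            doc_ids=payload["doc_ids"],
        )


def _record_id(record) -> str:
    for attr in ("doc_id", "journal_id"):
        if hasattr(record, attr):
            return getattr(record, attr)
    raise TypeError(f"cannot determine id of {record!r}")


def build_index(
    corpus: Iterable, stopwords: frozenset[str] | None = None
) -> InvertedIndex:
    """Index a corpus of documents or journal articles.

    Each record needs an id attribute (``doc_id`` or ``journal_id``) and a
    ``text`` attribute.  Raises ``ValueError`` on an empty corpus (the
    average length would be undefined).
    """
    df: dict[str, int] = {}
    postings: dict[str, dict[str, int]] = {}
    doc_len: dict[str, int] = {}
    doc_ids: list[str] = []
    for record in corpus:
        rec_id = _record_id(record)
        if rec_id in doc_len:
            raise ValueError(f"duplicate id {rec_id!r} in corpus")
        tokens = tokenize(record.text, stopwords)
        doc_len[rec_id] = len(tokens)
        doc_ids.append(rec_id)
        counts: dict[str, int] = {}
        for tok in tokens:
            counts[tok] = counts.get(tok, 0) + 1
        for term, tf in counts.items():
            df[term] = df.get(term, 0) + 1
            postings.setdefault(term, {})[rec_id] = tf
    if not doc_ids:
        raise ValueError("cannot index an empty corpus (avg_len undefined)")
    avg_len = sum(doc_len.values()) / len(doc_ids)
    return InvertedIndex(
        N=len(doc_ids),
        df=df,
        postings=postings,
        doc_len=doc_len,
        avg_len=avg_len,
        doc_ids=doc_ids,
    )


def bm25_score(
    index: InvertedIndex,
    query: str,
    doc_id: str,
    params: BM25Params = BM25Params(),
) -> float:
    """Okapi BM25 score of one document for one query.

    Terms absent from the document contribute zero; duplicate query terms
    are counted once.  Unknown ``doc_id`` raises ``KeyError``.
    """
    if doc_id not in index.doc_len:
        raise KeyError(f"doc_id {doc_id!r} not in index")
    l_d = index.doc_len[doc_id]
    score = 0.0
    # dict.fromkeys: unique terms in first-occurrence order, so the
    # floating-point summation order is reproducible across runs.
    for term in dict.fromkeys(tokenize(query)):
        posting = index.postings.get(term)
        if not posting or doc_id not in posting:
            continue
        tf = posting[doc_id]
        dft = index.df[term]
        idf = math.log((index.N - dft + 0.5) / (dft + 0.5))
        denom = tf + params.k1 * (1.0 - params.b + params.b * l_d / index.avg_len)
        score += idf * tf * (params.k1 + 1.0) / denom
    return score


def retrieve(
    index: InvertedIndex,
    query: str,
    k: int,
    params: BM25Params = BM25Params(),
) -> list[tuple[str, float]]:
    """Top-*k* documents by BM25, descending score, ties by ascending id.

    Only documents containing at least one query term are scored;
    documents whose score is exactly zero are excluded (negative scores
    from high-df terms are kept — raw idf, no clamping).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    candidates: dict[str, None] = {}
    for term in dict.fromkeys(tokenize(query)):
        for doc_id in index.postings.get(term, ()):
            candidates[doc_id] = None
    scored = [
        (doc_id, bm25_score(index, query, doc_id, params))
        for doc_id in candidates
    ]
    scored = [(d, s) for d, s in scored if s != 0.0]
    scored.sort(key=lambda pair: (-pair[1], pair[0]))
    return scored[:k]
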