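"""Text-embedding backends, cosine similarity, and medication/disease NER.

Two pluggable backend families sit behind the rest of the pipeline:

* **Embedding backends** map a text to a fixed-length real vector; any
  object with ``name``, ``dim`` and ``embed(text)`` fits the contract and
  must be deterministic (same text, same vector).  The reference backend
  here is a signed-feature-hashing bag-of-tokens embedding — fast, fully
  deterministic given its seed, and strong enough that token overlap
  translates into cosine similarity.  Production transformer encoders can
  be plugged in behind the same contract; when two backends are active
  (e.g. a general and a biomedical encoder) their cosines are averaged.

* **NER backends** extract an :class:`EntityProfile` — the sets of
  medication (mu) and disease (delta) mentions — from a text.  The
  reference backend is dictionary-driven with token-boundary phrase
  matching, which is exact on the entity vocabularies the synthetic
  corpora use; a model-based tagger can be substituted.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np

from .retrieval import tokenize

__all__ = [
    "cosine",
    "EmbeddingBackend",
    "HashEmbeddingBackend",
    "hash_embedding_backend",
    "ensemble_similarity",
    "EntityProfile",
    "NERBackend",
    "DictionaryNER",
    "extract_entities",
    "entities_match",
    "read_term_list",
]


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity in [-1, 1]; a zero vector yields 0.0 with a warning.

    A zero vector arises only from degenerate text (no tokens at all), so
    the 0.0 convention marks "no evidence of similarity" rather than an
    error.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"shape mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        warnings.warn(
            "cosine of a zero vector (degenerate text); returning 0.0",
            stacklevel=2,
        )
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


class EmbeddingBackend(Protocol):
    """Deterministic map from text to a vector of length ``dim``."""

    name: str
    dim: int

    def embed(self, text: str) -> np.ndarray: ...


class HashEmbeddingBackend:
    """Signed-feature-hashing bag-of-tokens embedding.

    Each token is hashed (keyed by ``seed``) to a coordinate in
    ``[0, dim)`` and a sign in {-1, +1}; a text embeds as the
    L2-normalized sum of its tokens' signed basis vectors.  Token overlap
    between two texts therefore raises their cosine, while disjoint
    vocabularies give near-orthogonal vectors for large ``dim``
    (hash collisions are the only cross-talk).
    """

    def __init__(self, dim: int = 512, seed: int = 0) -> None:
        if dim < 8:
            raise ValueError(f"dim must be >= 8, got {dim}")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = f"hash-{self.dim}-s{self.seed}"
        self._token_cache: dict[str, tuple[int, int]] = {}

    def _slot(self, token: str) -> tuple[int, int]:
        cached = self._token_cache.get(token)
        if cached is not None:
            return cached
        digest = hashlib.blake2b(
            token.encode("utf-8"),
            digest_size=16,
            key=str(self.seed).encode("utf-8"),
        ).digest()
        index = int.from_bytes(digest[:8], "big") % self.dim
        sign = 1 if digest[8] & 1 else -1
        self._token_cache[token] = (index, sign)
        return index, sign

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dim, dtype=float)
        for token in tokenize(text):
            index, sign = self._slot(token)
            vec[index] += sign
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        return vec


def hash_embedding_backend(dim: int = 512, seed: int = 0) -> HashEmbeddingBackend:
    """Factory for the deterministic hashing backend (see class docs)."""
    return HashEmbeddingBackend(dim=dim, seed=seed)


def ensemble_similarity(
    backends: Sequence[EmbeddingBackend], a: str, b: str
) -> float:
    """Mean cosine over the active embedding backends.

    With a single backend this is plain ``cosine(embed(a), embed(b))``;
    with two (e.g. general + biomedical encoders) the per-backend cosines
    are averaged.
    """
    if not backends:
        raise ValueError("at least one embedding backend required")
    return float(
        np.mean([cosine(be.embed(a), be.embed(b)) for be in backends])
    )


@dataclass(frozen=True)
class EntityProfile:
    """Normalized medication (mu) and disease (delta) mentions of a text."""

    medications: frozenset[str] = frozenset()
    diseases: frozenset[str] = frozenset()


class NERBackend(Protocol):
    def extract(self, text: str) -> EntityProfile: ...


def _normalize_term(term: str) -> str:
    return " ".join(tokenize(term))


class DictionaryNER:
    """Dictionary NER with token-boundary phrase matching.

    A term matches only as a contiguous token sequence, so a text
    mentioning "vitamin d" does not match the dictionary entry
    "vitamin c" even though they share a token.  Matching is
    case-insensitive via the shared tokenizer and order-independent.
    """

    def __init__(
        self, medications: Iterable[str], diseases: Iterable[str]
    ) -> None:
        self.medications = {
            _normalize_term(t) for t in medications if _normalize_term(t)
        }
        self.diseases = {
            _normalize_term(t) for t in diseases if _normalize_term(t)
        }
        self._med_tuples = {tuple(t.split()) for t in self.medications}
        self._dis_tuples = {tuple(t.split()) for t in self.diseases}
        lengths = {len(t) for t in self._med_tuples | self._dis_tuples}
        self._max_len = max(lengths, default=1)

    def extract(self, text: str) -> EntityProfile:
        tokens = tokenize(text)
        meds: set[str] = set()
        diss: set[str] = set()
        n = len(tokens)
        for i in range(n):
            for length in range(1, min(self._max_len, n - i) + 1):
                gram = tuple(tokens[i : i + length])
                if gram in self._med_tuples:
                    meds.add(" ".join(gram))
                if gram in self._dis_tuples:
                    diss.add(" ".join(gram))
        return EntityProfile(frozenset(meds), frozenset(diss))


def extract_entities(backend: NERBackend, text: str) -> EntityProfile:
    """Extract the medication/disease profile of a text (empty sets when
    nothing matches)."""
    return backend.extract(text)


def entities_match(
    query_profile: EntityProfile,
    sentence_profile: EntityProfile,
    mode: str = "strict",
) -> bool:
    """Whether two entity profiles correspond.

    ``strict`` (default) requires set equality per category — the literal
    reading of profile equality; two empty profiles match (no entities
    means there is no mismatch to penalize).  ``overlap`` instead requires
    a non-empty intersection in every category that is non-empty on both
    sides, a laxer alternative kept configurable.
    """
    if mode == "strict":
        return (
            query_profile.medications == sentence_profile.medications
            and query_profile.diseases == sentence_profile.diseases
        )
    if mode == "overlap":
        for qs, ss in (
            (query_profile.medications, sentence_profile.medications),
            (query_profile.diseases, sentence_profile.diseases),
        ):
            if qs and ss and not (qs & ss):
                return False
            if bool(qs) != bool(ss):
                return False
        return True
    raise ValueError(f"unknown entity-match mode {mode!r}")


def read_term_list(path: str | Path) -> list[str]:
    """Read a plain-text term list, one term per line, blanks skipped."""
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]
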