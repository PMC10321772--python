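"""Readers and writers for corpora, topics, relevance labels, and run files.

All formats are plain text so that fixtures can be generated and inspected
by hand:

* documents / journal articles — JSON-lines, one object per line with at
  least ``{"id", "text"}`` (documents may carry an optional ``"title"``);
* topics — JSON-lines with ``{"id", "title", "description", "answer",
  "narrative"}``;
* qrels — whitespace-separated columns ``topic_id doc_id usefulness
  credibility`` with strictly binary labels;
* run files — the standard six-column TREC format
  ``topic Q0 doc rank score tag``.

Text is normalized at read time to Unicode NFC with runs of whitespace
collapsed to single spaces; no case folding happens at I/O (tokenizers
decide case handling).
"""

from __future__ import annotations

import json
import unicodedata
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Document",
    "JournalArticle",
    "Topic",
    "QrelRecord",
    "CorpusFormatError",
    "read_documents",
    "read_topics",
    "read_qrels",
    "write_run",
    "read_run",
    "write_documents",
    "write_topics",
    "write_qrels",
]


class CorpusFormatError(ValueError):
    """A corpus, topic, qrel, or run file violates its documented format."""


@dataclass(frozen=True)
class Document:
    """One searchable document: an identifier and its free text."""

    doc_id: str
    text: str
    title: str | None = None


@dataclass(frozen=True)
class JournalArticle:
    """One trusted journal article used as a source of scientific evidence."""

    journal_id: str
    text: str


@dataclass(frozen=True)
class Topic:
    """A search topic: keyword title, question-form description, yes/no
    answer, and a free-text narrative.

    The description is the query string used for retrieval.
    """

    topic_id: str
    title: str
    description: str
    answer: str
    narrative: str


@dataclass(frozen=True)
class QrelRecord:
    """A (topic, document) judgement with binary usefulness and credibility."""

    topic_id: str
    doc_id: str
    usefulness: int
    credibility: int


def normalize_text(text: str) -> str:
    """Unicode NFC plus whitespace collapse; the only I/O-level cleanup."""
    return " ".join(unicodedata.normalize("NFC", text).split())


def _iter_jsonl(path: str | Path) -> Iterable[tuple[int, dict]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}: malformed JSON on line {lineno}: {exc}"
                ) from exc
            if not isinstance(obj, dict):
                raise CorpusFormatError(
                    f"{path}: line {lineno} is not a JSON object"
                )
            yield lineno, obj


def read_documents(
    path: str | Path, kind: str = "document"
) -> list[Document] | list[JournalArticle]:
    """Read a JSON-lines corpus of documents or journal articles.

    Parameters
    ----------
    path:
        JSON-lines file; each line needs string fields ``id`` and ``text``.
    kind:
        ``"document"`` or ``"journal"``; selects the record type.

    Order is preserved.  Duplicate ids and empty texts (after whitespace
    normalization) raise :class:`CorpusFormatError` naming the offending
    line numbers.
    """
    if kind not in ("document", "journal"):
        raise ValueError(f"kind must be 'document' or 'journal', got {kind!r}")
    records: list = []
    seen: dict[str, int] = {}
    for lineno, obj in _iter_jsonl(path):
        try:
            rec_id = str(obj["id"])
            text = normalize_text(str(obj["text"]))
        except KeyError as exc:
            raise CorpusFormatError(
                f"{path}: line {lineno} missing required field {exc}"
            ) from exc
        if not text:
            raise CorpusFormatError(
                f"{path}: line {lineno}: empty text for id {rec_id!r}"
            )
        if rec_id in seen:
            raise CorpusFormatError(
                f"{path}: duplicate id {rec_id!r} on lines {seen[rec_id]} "
                f"and {lineno}"
            )
        seen[rec_id] = lineno
        if kind == "document":
            title = obj.get("title")
            records.append(
                Document(rec_id, text, normalize_text(title) if title else None)
            )
        else:
            records.append(JournalArticle(rec_id, text))
    return records


def read_topics(path: str | Path) -> list[Topic]:
    """Read JSON-lines topics; the answer field is normalized to
    lowercase and must be ``yes`` or ``no``."""
    topics: list[Topic] = []
    seen: dict[str, int] = {}
    for lineno, obj in _iter_jsonl(path):
        for field in ("id", "title", "description", "answer", "narrative"):
            if field not in obj:
                raise CorpusFormatError(
                    f"{path}: line {lineno} missing field {field!r}"
                )
        description = normalize_text(str(obj["description"]))
        if not description:
            raise CorpusFormatError(
                f"{path}: line {lineno}: empty description (it is the query)"
            )
        answer = str(obj["answer"]).strip().lower()
        if answer not in ("yes", "no"):
            raise CorpusFormatError(
                f"{path}: line {lineno}: answer must be yes/no, "
                f"got {obj['answer']!r}"
            )
        topic_id = str(obj["id"])
        if topic_id in seen:
            raise CorpusFormatError(
                f"{path}: duplicate topic id {topic_id!r} on lines "
                f"{seen[topic_id]} and {lineno}"
            )
        seen[topic_id] = lineno
        topics.append(
            Topic(
                topic_id,
                normalize_text(str(obj["title"])),
                description,
                answer,
                normalize_text(str(obj["narrative"])),
            )
        )
    return topics


def read_qrels(path: str | Path) -> list[QrelRecord]:
    """Read whitespace-separated qrels with binary usefulness/credibility."""
    records: list[QrelRecord] = []
    seen: dict[tuple[str, str], int] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 4 columns, "
                    f"got {len(parts)}"
                )
            topic_id, doc_id, use_s, cred_s = parts
            labels = []
            for name, value in (("usefulness", use_s), ("credibility", cred_s)):
                if value not in ("0", "1"):
                    raise CorpusFormatError(
                        f"{path}: line {lineno}: {name} label must be 0 or 1, "
                        f"got {value!r}"
                    )
                labels.append(int(value))
            key = (topic_id, doc_id)
            if key in seen:
                raise CorpusFormatError(
                    f"{path}: duplicate (topic, doc) pair {key} on lines "
                    f"{seen[key]} and {lineno}"
                )
            seen[key] = lineno
            records.append(QrelRecord(topic_id, doc_id, labels[0], labels[1]))
    return records


def write_run(
    rankings: Mapping[str, Sequence],
    path: str | Path,
    tag: str = "truthsearch",
) -> None:
    """Write per-topic rankings as a six-column TREC run file.

    ``rankings`` maps topic id to a list of scored documents (anything with
    ``doc_id`` and ``rsv`` attributes) already sorted by descending RSV;
    unsorted input raises ``ValueError``.  Ranks are written starting at 1.
    """
    with open(path, "w", encoding="utf-8") as fh:
        for topic_id in rankings:
            docs = rankings[topic_id]
            rsvs = [d.rsv for d in docs]
            if any(a < b for a, b in zip(rsvs, rsvs[1:])):
                raise ValueError(
                    f"ranking for topic {topic_id!r} is not sorted by "
                    "descending RSV; sort before writing"
                )
            for rank, doc in enumerate(docs, start=1):
                fh.write(
                    f"{topic_id} Q0 {doc.doc_id} {rank} {doc.rsv:.6f} {tag}\n"
                )


def read_run(path: str | Path) -> dict[str, list[tuple[str, int, float]]]:
    """Read a TREC run file back as ``{topic: [(doc, rank, score), ...]}``."""
    out: dict[str, list[tuple[str, int, float]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 6 columns, "
                    f"got {len(parts)}"
                )
            topic_id, _q0, doc_id, rank, score, _tag = parts
            out.setdefault(topic_id, []).append(
                (doc_id, int(rank), float(score))
            )
    return out


def write_documents(
    records: Iterable[Document | JournalArticle], path: str | Path
) -> None:
    """Write documents or journal articles as JSON-lines (reader inverse)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            if isinstance(rec, Document):
                obj: dict = {"id": rec.doc_id, "text": rec.text}
                if rec.title is not None:
                    obj["title"] = rec.title
            else:
                obj = {"id": rec.journal_id, "text": rec.text}
            fh.write(json.dumps(obj, sort_keys=True) + "\n")


def write_topics(topics: Iterable[Topic], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in topics:
            fh.write(
                json.dumps(
                    {
                        "id": t.topic_id,
                        "title": t.title,
                        "description": t.description,
                        "answer": t.answer,
                        "narrative": t.narrative,
                    },
                    sort_keys=True,
                )
                + "\n"
            )


def write_qrels(records: Iterable[QrelRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.topic_id} {r.doc_id} {r.usefulness} {r.credibility}\n")
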