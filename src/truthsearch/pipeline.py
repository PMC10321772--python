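"""Wiring of the full pipeline: index, search, explain, evaluate.

The CLI subcommands are thin wrappers around the functions here, so every
stage is scriptable from Python as well.  All randomness flows from the
seed in :class:`~truthsearch.config.RunConfig`; two runs with identical
inputs and config produce byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

from .config import RunConfig
from .corpus_io import (
    Document,
    JournalArticle,
    QrelRecord,
    Topic,
    write_run,
)
from .evaluation import CVResult, cross_validate, document_score
from .explain import Explanation, explain_document, write_explanations
from .ranking import ScoredDoc, rank_documents
from .representation import DictionaryNER, HashEmbeddingBackend
from .retrieval import InvertedIndex, build_index, retrieve

__all__ = [
    "search_all",
    "explain_pairs",
    "score_dataset",
    "evaluate_corpus",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


def _doc_map(documents: Sequence[Document]) -> dict[str, Document]:
    return {d.doc_id: d for d in documents}


def _journal_map(journals: Sequence[JournalArticle]) -> dict[str, JournalArticle]:
    return {j.journal_id: j for j in journals}


def search_all(
    topics: Sequence[Topic],
    documents: Sequence[Document],
    journals: Sequence[JournalArticle],
    cfg: RunConfig,
    doc_index: InvertedIndex | None = None,
    journal_index: InvertedIndex | None = None,
) -> dict[str, list[ScoredDoc]]:
    """Rank documents for every topic by fused topicality + truthfulness."""
    doc_index = doc_index or build_index(documents)
    journal_index = journal_index or build_index(journals)
    backend = HashEmbeddingBackend(dim=cfg.embed_dim, seed=cfg.seed)
    docs = _doc_map(documents)
    jmap = _journal_map(journals)
    return {
        topic.topic_id: rank_documents(
            topic,
            doc_index,
            journal_index,
            docs,
            jmap,
            backend,
            n_docs=cfg.n_docs,
            n_journals=cfg.n_journals,
            weights_scheme=cfg.weights_scheme,
            fusion=cfg.fusion,
            params=cfg.bm25_params,
        )
        for topic in topics
    }


def explain_pairs(
    pairs: Sequence[tuple[str, str]],
    topics: Sequence[Topic],
    documents: Sequence[Document],
    journals: Sequence[JournalArticle],
    cfg: RunConfig,
    ner: DictionaryNER | None,
) -> list[Explanation]:
    """Explain a list of (topic_id, doc_id) pairs.

    Journal articles are retrieved once per topic (top ``n_journals`` by
    BM25 on the topic description) and shared by all of that topic's
    documents.
    """
    topic_map = {t.topic_id: t for t in topics}
    docs = _doc_map(documents)
    jmap = _journal_map(journals)
    journal_index = build_index(journals)
    backend = HashEmbeddingBackend(dim=cfg.embed_dim, seed=cfg.seed)
    journal_cache: dict[str, list[JournalArticle]] = {}
    out: list[Explanation] = []
    for topic_id, doc_id in pairs:
        topic = topic_map[topic_id]
        if topic_id not in journal_cache:
            hits = retrieve(
                journal_index,
                topic.description,
                cfg.n_journals,
                cfg.bm25_params,
            )
            journal_cache[topic_id] = [jmap[jid] for jid, _ in hits]
        out.append(
            explain_document(
                topic,
                docs[doc_id],
                journal_cache[topic_id],
                cfg.explain,
                ner=ner,
                backends=backend,
                bm25_params=cfg.bm25_params,
            )
        )
    return out


def score_dataset(
    explanations: Sequence[Explanation],
    qrels: Sequence[QrelRecord],
    cfg: RunConfig,
) -> list[tuple[str, str, float, int]]:
    """Join explanations with credibility labels into a scored dataset.

    Rows are (topic_id, doc_id, document score, credibility); pairs
    without a label are dropped with a log message.
    """
    labels = {(q.topic_id, q.doc_id): q.credibility for q in qrels}
    agg = cfg.aggregation
    dataset = []
    skipped = 0
    for ex in explanations:
        key = (ex.topic_id, ex.doc_id)
        if key not in labels:
            skipped += 1
            continue
        dataset.append((*key, document_score(ex, agg), labels[key]))
    if skipped:
        logger.info("dropped %d unlabeled (topic, doc) pairs", skipped)
    return dataset


def evaluate_corpus(
    topics: Sequence[Topic],
    documents: Sequence[Document],
    journals: Sequence[JournalArticle],
    qrels: Sequence[QrelRecord],
    cfg: RunConfig,
    ner: DictionaryNER | None = None,
) -> CVResult:
    """End-to-end classification evaluation over all labeled pairs."""
    pairs = [(q.topic_id, q.doc_id) for q in qrels]
    explanations = explain_pairs(pairs, topics, documents, journals, cfg, ner)
    dataset = score_dataset(explanations, qrels, cfg)
    return cross_validate(dataset, n_folds=cfg.folds, seed=cfg.seed)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _metrics_payload(cfg: RunConfig, result: CVResult, n: int) -> dict:
    return {
        "n": n,
        "n_docs": cfg.n_docs,
        "n_journals": cfg.n_journals,
        "n_passages": cfg.n_passages,
        "strategy": cfg.strategy,
        "ner": cfg.use_ner,
        "mode": cfg.mode,
        "folds": cfg.folds,
        "f1": result.mean.f1,
        "gm": result.mean.gm,
        "auc": result.mean.auc,
        "std": {
            "f1": result.std.f1,
            "gm": result.std.gm,
            "auc": result.std.auc,
        },
        "per_fold": [
            {"f1": m.f1, "gm": m.gm, "auc": m.auc} for m in result.per_fold
        ],
    }


def run_pipeline(
    cfg: RunConfig,
    topics: Sequence[Topic],
    documents: Sequence[Document],
    journals: Sequence[JournalArticle],
    qrels: Sequence[QrelRecord],
    ner: DictionaryNER | None,
    out_dir: str | Path,
    input_paths: Mapping[str, Path] | None = None,
) -> dict[str, Path]:
    """Search, explain, and evaluate; write all artifacts plus a manifest.

    Artifacts: ``run.txt`` (TREC run), ``explanations.jsonl``,
    ``metrics.json``, and ``manifest.json`` recording the config hash,
    seed, and input checksums.  Deterministic given config and inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {
        "run": out / "run.txt",
        "explanations": out / "explanations.jsonl",
        "metrics": out / "metrics.json",
        "manifest": out / "manifest.json",
    }

    rankings = search_all(topics, documents, journals, cfg)
    write_run(rankings, artifacts["run"])

    labeled = {(q.topic_id, q.doc_id) for q in qrels}
    pairs = [
        (topic_id, sd.doc_id)
        for topic_id, ranked in rankings.items()
        for sd in ranked
    ]
    explanations = explain_pairs(
        pairs, topics, documents, journals, cfg, ner
    )
    write_explanations(explanations, artifacts["explanations"])

    dataset = score_dataset(explanations, qrels, cfg)
    result = cross_validate(dataset, n_folds=cfg.folds, seed=cfg.seed)
    with open(artifacts["metrics"], "w", encoding="utf-8") as fh:
        json.dump(
            _metrics_payload(cfg, result, len(dataset)),
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")

    manifest = {
        "config": cfg.to_dict(),
        "config_sha256": cfg.digest(),
        "seed": cfg.seed,
        "n_labeled_pairs": len(dataset),
        "n_retrieved_pairs": len(pairs),
        "n_retrieved_labeled": sum(1 for p in pairs if p in labeled),
        "inputs": {
            name: _sha256(Path(p)) for name, p in (input_paths or {}).items()
        },
        "artifacts": sorted(
            name for name in artifacts if name != "manifest"
        ),
    }
    with open(artifacts["manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return artifacts
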