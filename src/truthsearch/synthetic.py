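"""Self-contained synthetic corpora with controlled truthfulness structure.

The generator emulates the data layout of a consumer-health-search
benchmark at desk scale: topics (keyword title, question description,
yes/no answer, narrative), an open document collection, a trusted journal
corpus, binary usefulness/credibility labels, and medication/disease
dictionaries.  It encodes exactly the mechanism the retrieval and
explanation pipeline exploits:

* every topic pairs one medication with one disease in a *fact sentence*;
* the topic's journal article embeds the fact sentence verbatim inside
  formal filler prose;
* truthful documents (credibility 1) carry a token-dropout paraphrase of
  the fact sentence that preserves both entities;
* misinformation documents (credibility 0) carry a corrupted variant —
  by default the medication is swapped for a different one
  (``entity_swap``), so the text stays lexically close to the evidence
  but disagrees on the named entities; ``negation`` and ``random_text``
  corruptions are available as harder / easier alternatives.

Document filler and journal filler are drawn from separate sentence
pools with minimal shared vocabulary so an off-topic document sentence
can never be near-identical to a journal sentence; this keeps the
truthful / misinformation score distributions separable by construction.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .corpus_io import (
    Document,
    JournalArticle,
    QrelRecord,
    Topic,
    write_documents,
    write_qrels,
    write_topics,
)

__all__ = [
    "SynthConfig",
    "SyntheticCorpus",
    "make_entity_vocab",
    "generate_corpus",
    "write_corpus",
]

_MEDICATIONS = [
    "ibuprofen",
    "paracetamol",
    "aspirin",
    "amoxicillin",
    "vitamin c",
    "vitamin d",
    "zinc",
    "metformin",
    "insulin",
    "warfarin",
    "atorvastatin",
    "hydroxychloroquine",
    "remdesivir",
    "dexamethasone",
    "azithromycin",
    "melatonin",
    "loratadine",
    "omeprazole",
    "prednisone",
    "salbutamol",
    "lisinopril",
    "naproxen",
    "cetirizine",
    "fluoxetine",
]

_DISEASES = [
    "covid-19",
    "influenza",
    "diabetes",
    "hypertension",
    "asthma",
    "migraine",
    "arthritis",
    "pneumonia",
    "bronchitis",
    "eczema",
    "malaria",
    "measles",
    "anemia",
    "gout",
    "insomnia",
    "obesity",
    "depression",
    "osteoporosis",
    "dementia",
    "tuberculosis",
    "hepatitis",
    "psoriasis",
    "sinusitis",
    "tonsillitis",
]

# Casual register for documents, formal register for journals; the two
# pools share almost no vocabulary (see module docstring).
_DOC_FILLER = [
    "readers keep asking what this news could mean day to day.",
    "social media posts about it spread quickly last week.",
    "our newsletter covers wellness tips every single morning.",
    "several commenters shared very personal stories below.",
    "local pharmacies reported unusually busy afternoons lately.",
    "nobody expected so much attention around one short headline.",
    "you can subscribe anytime if similar topics interest you.",
    "friends often forward these stories straight to each other.",
    "sales of home remedies jumped right after publication.",
    "a lively debate continues across neighborhood forums.",
]

_JOURNAL_FILLER = [
    "the randomized cohort was monitored across twelve months.",
    "baseline characteristics were balanced between both groups.",
    "statistical significance was assessed with standard tests.",
    "adverse events remained within expected safety margins.",
    "methodological limitations are discussed in the appendix.",
    "the protocol received institutional ethics approval beforehand.",
    "follow-up examinations occurred at regular scheduled intervals.",
    "data were collected under strict double-blind conditions.",
    "enrollment criteria excluded participants with comorbidities.",
    "replication in larger samples remains a priority of future work.",
]

# Fact-sentence template pieces; entity tokens are inserted between them
# and are never dropped by the paraphrase noise.
_FACT_PREFIX: list[str] = []
_FACT_MIDDLE = ["is", "an", "effective", "treatment", "option", "for"]
_FACT_SUFFIX = ["according", "to", "recent", "peer", "reviewed", "studies"]


@dataclass(frozen=True)
class SynthConfig:
    """Generator knobs; defaults are the study conditions of the package.

    ``paraphrase_noise`` is the per-token dropout rate applied to the
    non-entity tokens of a document's fact sentence, ``misinformation_
    fraction`` the share of credibility-0 documents per topic, and
    ``corruption_mode`` how misinformation disagrees with the evidence.
    """

    n_topics: int = 8
    docs_per_topic: int = 40
    journals_per_topic: int = 1
    misinformation_fraction: float = 0.5
    paraphrase_noise: float = 0.1
    corruption_mode: str = "entity_swap"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_topics, self.docs_per_topic, self.journals_per_topic) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 < self.misinformation_fraction < 1.0:
            raise ValueError(
                "misinformation_fraction must lie strictly in (0, 1)"
            )
        if not 0.0 <= self.paraphrase_noise <= 1.0:
            raise ValueError("paraphrase_noise must lie in [0, 1]")
        if self.corruption_mode not in ("entity_swap", "negation", "random_text"):
            raise ValueError(
                f"unknown corruption_mode {self.corruption_mode!r}"
            )


@dataclass(frozen=True)
class SyntheticCorpus:
    """A generated benchmark: corpora, topics, labels, and dictionaries."""

    documents: tuple[Document, ...]
    journals: tuple[JournalArticle, ...]
    topics: tuple[Topic, ...]
    qrels: tuple[QrelRecord, ...]
    medications: tuple[str, ...]
    diseases: tuple[str, ...]


def make_entity_vocab(seed: int = 0) -> tuple[list[str], list[str]]:
    """Seed-shuffled medication and disease vocabularies.

    Both lists hold >= 20 distinct lowercase terms (some multi-token,
    some hyphenated) and are disjoint across categories; shuffling is
    deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    meds = list(_MEDICATIONS)
    diseases = list(_DISEASES)
    rng.shuffle(meds)
    rng.shuffle(diseases)
    return meds, diseases


def _fact_tokens(med: str, disease: str) -> tuple[list[str], set[int]]:
    """Fact sentence as tokens plus the indices of protected entity tokens."""
    tokens: list[str] = []
    protected: set[int] = set()
    for part, is_entity in (
        (_FACT_PREFIX, False),
        (med.split(), True),
        (_FACT_MIDDLE, False),
        (disease.split(), True),
        (_FACT_SUFFIX, False),
    ):
        for tok in part:
            if is_entity:
                protected.add(len(tokens))
            tokens.append(tok)
    return tokens, protected


def _paraphrase(
    tokens: list[str], protected: set[int], noise: float, rng
) -> str:
    kept = [
        tok
        for i, tok in enumerate(tokens)
        if i in protected or rng.random() >= noise
    ]
    return " ".join(kept) + "."


def generate_corpus(cfg: SynthConfig) -> SyntheticCorpus:
    """Generate documents, journal articles, topics, qrels, and dictionaries.

    Per topic: one fact sentence pairing a medication and a disease; the
    topic's journal articles embed it verbatim; truthful documents carry
    an entity-preserving paraphrase; misinformation documents carry the
    configured corruption.  Usefulness is 1 for every on-topic document
    and credibility follows the construction.  Raises ``ValueError`` when
    ``docs_per_topic`` is too small to realize ``misinformation_fraction``
    with at least one document of each class.
    """
    n_mis = round(cfg.docs_per_topic * cfg.misinformation_fraction)
    if n_mis < 1 or n_mis >= cfg.docs_per_topic:
        raise ValueError(
            f"docs_per_topic={cfg.docs_per_topic} cannot honor "
            f"misinformation_fraction={cfg.misinformation_fraction} with "
            "at least one document of each class"
        )
    rng = np.random.default_rng(cfg.seed)
    meds, diseases = make_entity_vocab(cfg.seed)

    documents: list[Document] = []
    journals: list[JournalArticle] = []
    topics: list[Topic] = []
    qrels: list[QrelRecord] = []

    for ti in range(cfg.n_topics):
        med = meds[ti % len(meds)]
        disease = diseases[ti % len(diseases)]
        topic_id = f"t{ti:03d}"
        fact_tokens, protected = _fact_tokens(med, disease)
        fact_sentence = " ".join(fact_tokens) + "."

        topics.append(
            Topic(
                topic_id=topic_id,
                title=f"{med} {disease}",
                description=(
                    f"can {med} provide an effective treatment for {disease}?"
                ),
                answer=str(rng.choice(["yes", "no"])),
                narrative=(
                    f"helpful documents discuss whether {med} treats "
                    f"{disease}; harmful documents promote unsupported claims."
                ),
            )
        )

        for ji in range(cfg.journals_per_topic):
            lead = rng.choice(len(_JOURNAL_FILLER), size=2, replace=False)
            tail = rng.choice(len(_JOURNAL_FILLER), size=2, replace=False)
            sentences = (
                [_JOURNAL_FILLER[i] for i in lead]
                + [fact_sentence]
                + [_JOURNAL_FILLER[i] for i in tail]
            )
            journals.append(
                JournalArticle(f"j{ti:03d}-{ji}", " ".join(sentences))
            )

        flags = [False] * (cfg.docs_per_topic - n_mis) + [True] * n_mis
        rng.shuffle(flags)
        for di, is_mis in enumerate(flags):
            if is_mis:
                if cfg.corruption_mode == "entity_swap":
                    alternatives = [m for m in meds if m != med]
                    swap = alternatives[rng.integers(len(alternatives))]
                    tokens, prot = _fact_tokens(swap, disease)
                    core = _paraphrase(tokens, prot, cfg.paraphrase_noise, rng)
                elif cfg.corruption_mode == "negation":
                    tokens, prot = _fact_tokens(med, disease)
                    negated = []
                    shift_prot = set()
                    for i, tok in enumerate(tokens):
                        if tok == "is":
                            negated.extend(["is", "not"])
                            continue
                        if i in prot:
                            shift_prot.add(len(negated))
                        negated.append(tok)
                    core = _paraphrase(
                        negated, shift_prot, cfg.paraphrase_noise, rng
                    )
                else:  # random_text: no evidence-related sentence at all
                    core = _DOC_FILLER[rng.integers(len(_DOC_FILLER))]
            else:
                tokens, prot = _fact_tokens(med, disease)
                core = _paraphrase(tokens, prot, cfg.paraphrase_noise, rng)
            lead = rng.choice(len(_DOC_FILLER), size=2, replace=False)
            tail = rng.choice(len(_DOC_FILLER), size=2, replace=False)
            text = " ".join(
                [_DOC_FILLER[i] for i in lead]
                + [core]
                + [_DOC_FILLER[i] for i in tail]
            )
            doc_id = f"d{ti:03d}-{di:03d}"
            documents.append(Document(doc_id, text))
            qrels.append(
                QrelRecord(
                    topic_id=topic_id,
                    doc_id=doc_id,
                    usefulness=1,
                    credibility=0 if is_mis else 1,
                )
            )

    return SyntheticCorpus(
        documents=tuple(documents),
        journals=tuple(journals),
        topics=tuple(topics),
        qrels=tuple(qrels),
        medications=tuple(meds),
        diseases=tuple(diseases),
    )


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write a generated corpus in the package's text formats.

    Creates ``docs.jsonl``, ``journals.jsonl``, ``topics.jsonl``,
    ``qrels.txt``, ``medications.txt``, and ``diseases.txt`` under
    ``out_dir`` and returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "docs": out / "docs.jsonl",
        "journals": out / "journals.jsonl",
        "topics": out / "topics.jsonl",
        "qrels": out / "qrels.txt",
        "medications": out / "medications.txt",
        "diseases": out / "diseases.txt",
    }
    write_documents(corpus.documents, paths["docs"])
    write_documents(corpus.journals, paths["journals"])
    write_topics(corpus.topics, paths["topics"])
    write_qrels(corpus.qrels, paths["qrels"])
    for key, terms in (
        ("medications", corpus.medications),
        ("diseases", corpus.diseases),
    ):
        with open(paths[key], "w", encoding="utf-8") as fh:
            for term in terms:
                fh.write(term + "\n")
    return paths
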