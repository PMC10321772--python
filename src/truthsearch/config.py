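"""Run configuration: every tunable of the pipeline in one validated record."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .evaluation import AggregationConfig
from .explain import ExplainConfig
from .ranking import FusionConfig
from .retrieval import BM25Params

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline tunables with their defaults.

    Field groups map onto the stage configs (BM25, fusion, explanation,
    aggregation); validation happens eagerly on construction by building
    each stage config, so an invalid value fails before any work starts.
    """

    # retrieval
    k1: float = 1.2
    b: float = 0.75
    n_docs: int = 20
    n_journals: int = 1
    # fusion
    weights_scheme: str = "reciprocal"
    w_trs: float = 0.5
    w_its: float = 0.5
    topicality_normalization: str = "minmax"
    # explanation
    strategy: str = "embedding"
    use_ner: bool = True
    w_d: float = 0.5
    n_passages: int = 5
    n_evidence: int = 5
    # evaluation
    mode: str = "max"
    passage_combine: str | None = None
    folds: int = 5
    # randomness / embedding
    seed: int = 0
    embed_dim: int = 512

    def __post_init__(self) -> None:
        self.bm25_params  # noqa: B018 — construction validates
        self.fusion
        self.explain
        self.aggregation
        if self.n_docs < 1 or self.n_journals < 1:
            raise ValueError("n_docs and n_journals must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.embed_dim < 8:
            raise ValueError("embed_dim must be >= 8")
        if self.weights_scheme not in ("reciprocal", "linear", "uniform"):
            raise ValueError(f"unknown weights_scheme {self.weights_scheme!r}")

    @property
    def bm25_params(self) -> BM25Params:
        return BM25Params(k1=self.k1, b=self.b)

    @property
    def fusion(self) -> FusionConfig:
        return FusionConfig(
            w_trs=self.w_trs,
            w_its=self.w_its,
            topicality_normalization=self.topicality_normalization,
        )

    @property
    def explain(self) -> ExplainConfig:
        return ExplainConfig(
            strategy=self.strategy,
            use_ner=self.use_ner,
            w_d=self.w_d,
            n_passages=self.n_passages,
            n_evidence=self.n_evidence,
        )

    @property
    def aggregation(self) -> AggregationConfig:
        return AggregationConfig(
            mode=self.mode, passage_combine=self.passage_combine
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration (for run manifests)."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode("utf-8")).hexdigest()

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update(overrides)
        return cls(**data)
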