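"""Document truthfulness classification from passage-evidence similarities.

The explainability pipeline assigns every (topic, document) pair a set of
query-relevant passages, each carrying sigma similarities to its journal
evidence sentences.  Collapsing those similarities into one score per
document (mean or max over evidence, then combined across passages) and
thresholding it yields a binary truthfulness prediction, which is
evaluated against binary credibility labels under k-fold cross-validation
with F1, geometric mean (sqrt of sensitivity x specificity), and AUC.
The only fitted quantity is the decision threshold, chosen on the
training folds to maximize F1.

A Fleiss' kappa utility for fixed-rater categorical agreement is included
for analysing multi-rater annotation studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score, roc_auc_score

from .explain import Explanation

__all__ = [
    "AggregationConfig",
    "MetricSet",
    "CVResult",
    "document_score",
    "fit_threshold",
    "compute_metrics",
    "cross_validate",
    "fleiss_kappa",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AggregationConfig:
    """How sigma similarities collapse to one score per document.

    ``mode`` aggregates each passage's evidence scores (mean or max);
    ``passage_combine`` merges the per-passage aggregates across the P
    passages.  By default it mirrors ``mode`` (max with max, mean with
    mean); both are configurable independently.
    """

    mode: str = "max"
    passage_combine: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("mean", "max"):
            raise ValueError(f"mode must be 'mean' or 'max', got {self.mode!r}")
        if self.passage_combine not in (None, "mean", "max"):
            raise ValueError(
                f"passage_combine must be 'mean' or 'max', "
                f"got {self.passage_combine!r}"
            )

    @property
    def combine(self) -> str:
        return self.passage_combine or self.mode


@dataclass(frozen=True)
class MetricSet:
    """F1, geometric mean, and AUC (AUC may be NaN when undefined)."""

    f1: float
    gm: float
    auc: float


@dataclass(frozen=True)
class CVResult:
    """Per-fold metrics plus their across-fold mean and standard deviation."""

    per_fold: tuple[MetricSet, ...]
    mean: MetricSet
    std: MetricSet


def document_score(
    explanation: Explanation, cfg: AggregationConfig = AggregationConfig()
) -> float:
    """Collapse an explanation's sigma similarities to one document score.

    Per passage: mean or max of its evidence scores (``cfg.mode``); across
    passages: ``cfg.combine``.  A document with no evidence at all scores
    0.0 with a warning.
    """
    per_passage: list[float] = []
    for items in explanation.evidence:
        scores = [e.score for e in items]
        if not scores:
            continue
        per_passage.append(
            max(scores) if cfg.mode == "max" else sum(scores) / len(scores)
        )
    if not per_passage:
        logger.warning(
            "no evidence for document %s (topic %s); score 0.0",
            explanation.doc_id,
            explanation.topic_id,
        )
        return 0.0
    if cfg.combine == "max":
        return max(per_passage)
    return sum(per_passage) / len(per_passage)


def fit_threshold(
    train_scores: Sequence[float], train_labels: Sequence[int]
) -> float:
    """Decision threshold maximizing training F1 (predict positive when
    score >= theta).

    The candidate grid is the midpoints between consecutive sorted unique
    scores; ties in F1 resolve to the smallest theta.  Both classes must
    be present.  If all training scores coincide the grid is empty and
    theta is that single value (predict-all-positive), logged.
    """
    scores = list(map(float, train_scores))
    labels = list(map(int, train_labels))
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    if len(set(labels)) < 2:
        raise ValueError("training labels must contain both classes")
    uniq = sorted(set(scores))
    if len(uniq) == 1:
        logger.warning(
            "all training scores identical (%.6f); threshold degenerate",
            uniq[0],
        )
        return uniq[0]
    grid = [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]
    arr = np.asarray(scores)
    lab = np.asarray(labels)
    best_theta = grid[0]
    best_f1 = -1.0
    for theta in grid:
        preds = (arr >= theta).astype(int)
        f1 = f1_score(lab, preds, zero_division=1.0)
        if f1 > best_f1 + 1e-12:
            best_f1 = f1
            best_theta = theta
    return float(best_theta)


def compute_metrics(
    scores: Sequence[float],
    predictions: Sequence[int],
    labels: Sequence[int],
) -> MetricSet:
    """F1 / GM / AUC of binary predictions and the underlying scores.

    Positive class is credible (= truthful).  GM is
    sqrt(sensitivity * specificity).  AUC is the Mann-Whitney pairwise
    ordering statistic on the raw scores (ties count 1/2); it requires
    both classes among the labels and raises ``ValueError`` otherwise.
    The degenerate F1 case TP = FP = FN = 0 is defined as 1.0 and logged.
    """
    scores = np.asarray(scores, dtype=float)
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores) == len(predictions) == len(labels)):
        raise ValueError("scores, predictions, labels must have equal length")
    tn, fp, fn, tp = confusion_matrix(
        labels, predictions, labels=[0, 1]
    ).ravel()
    if tp + fp + fn == 0:
        logger.info("no positives anywhere; F1 defined as 1.0 by convention")
        f1 = 1.0
    else:
        f1 = 2.0 * tp / (2.0 * tp + fp + fn)
    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    specificity = tn / (tn + fp) if (tn + fp) else 0.0
    gm = math.sqrt(sensitivity * specificity)
    if len(set(labels.tolist())) < 2:
        raise ValueError("AUC undefined: labels contain a single class")
    auc = float(roc_auc_score(labels, scores))
    return MetricSet(f1=float(f1), gm=float(gm), auc=auc)


def _nan_metricset(values: Sequence[MetricSet], reducer) -> MetricSet:
    def red(attr: str) -> float:
        arr = np.asarray([getattr(m, attr) for m in values], dtype=float)
        return float(reducer(arr))

    return MetricSet(f1=red("f1"), gm=red("gm"), auc=red("auc"))


def cross_validate(
    dataset: Sequence[tuple[str, str, float, int]],
    n_folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """K-fold cross-validated classification of document scores.

    ``dataset`` rows are (topic_id, doc_id, score, credibility).  Pairs
    are shuffled with ``seed`` and split into ``n_folds`` folds whose
    sizes differ by at most one; per fold, the threshold is fitted on the
    remaining folds and metrics are computed on the held-out fold.  A
    held-out fold with single-class labels gets AUC = NaN (logged) and
    NaN-aware mean/std are reported.  Fully deterministic given the seed
    and the dataset order.
    """
    n = len(dataset)
    if n_folds < 2:
        raise ValueError(f"n_folds must be >= 2, got {n_folds}")
    if n < n_folds:
        raise ValueError(f"dataset of size {n} cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    scores = np.asarray([row[2] for row in dataset], dtype=float)
    labels = np.asarray([row[3] for row in dataset], dtype=int)
    per_fold: list[MetricSet] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate(
            [f for j, f in enumerate(folds) if j != i]
        )
        theta = fit_threshold(scores[train_idx], labels[train_idx])
        preds = (scores[test_idx] >= theta).astype(int)
        test_labels = labels[test_idx]
        if len(set(test_labels.tolist())) < 2:
            logger.warning(
                "fold %d has single-class labels; AUC reported as NaN", i
            )
            tn_fp_fn_tp = confusion_matrix(
                test_labels, preds, labels=[0, 1]
            ).ravel()
            tn, fp, fn, tp = tn_fp_fn_tp
            f1 = 1.0 if (tp + fp + fn) == 0 else 2.0 * tp / (2 * tp + fp + fn)
            sens = tp / (tp + fn) if (tp + fn) else 0.0
            spec = tn / (tn + fp) if (tn + fp) else 0.0
            per_fold.append(
                MetricSet(float(f1), math.sqrt(sens * spec), float("nan"))
            )
        else:
            per_fold.append(
                compute_metrics(scores[test_idx], preds, test_labels)
            )
    mean = _nan_metricset(per_fold, np.nanmean)
    std = _nan_metricset(per_fold, np.nanstd)
    return CVResult(tuple(per_fold), mean, std)


def fleiss_kappa(ratings: Sequence[Sequence[int]], n_raters: int) -> float:
    """Fleiss' kappa for a fixed number of raters.

    ``ratings`` is an items x categories count matrix; every row must sum
    to ``n_raters`` and at least two items are required.  Returns
    kappa = (P_bar - P_e) / (1 - P_e).  When every rating falls in a
    single category P_e = 1; kappa is then defined as 1.0 if agreement is
    also perfect (P_bar = 1) and raises ``ValueError`` otherwise.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2:
        raise ValueError("ratings must be a 2-D matrix with >= 2 items")
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    row_sums = table.sum(axis=1)
    if not np.all(row_sums == n_raters):
        raise ValueError(f"every row must sum to n_raters={n_raters}")
    n_items = table.shape[0]
    # per-item agreement: fraction of concordant rater pairs
    p_i = (np.sum(table * (table - 1.0), axis=1)) / (n_raters * (n_raters - 1))
    p_bar = float(np.mean(p_i))
    p_j = table.sum(axis=0) / (n_items * n_raters)
    p_e = float(np.sum(p_j**2))
    if abs(1.0 - p_e) < 1e-15:
        if abs(1.0 - p_bar) < 1e-15:
            return 1.0
        raise ValueError("kappa undefined: expected agreement P_e equals 1")
    return (p_bar - p_e) / (1.0 - p_e)
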