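"""AUROC / AUPR scoring of a ranked edge list against a gold standard.

Predictions are compared with the true network over all ordered
off-diagonal gene pairs (optionally restricted to candidate regulator
rows).  AUROC uses the Mann-Whitney formulation, P(score_pos > score_neg)
+ 0.5 P(equal); AUPR uses the average-precision (stepwise) convention,
with tied scores expanded in the deterministic (regulator, target) index
order used everywhere in this package.  The DREAM organizers' p-values and
final "score" aggregate require their empirical null-distribution files
and are not computed here.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_io import EdgeSet
from .errors import UndefinedMetricError

__all__ = ["EvaluationResult", "auroc", "aupr", "evaluate"]


@dataclasses.dataclass(frozen=True)
class EvaluationResult:
    """Edge-ranking accuracy of one prediction against one gold standard."""

    auroc: float
    aupr: float
    n_edges_scored: int
    n_positives: int


def auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve (rank statistic; tie-aware)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if labels.min() == labels.max():
        raise UndefinedMetricError("undefined metric: need both positive and negative labels")
    return float(roc_auc_score(labels, scores))


def aupr(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve, average-precision convention.

    Items are ranked by decreasing score with ties broken by original
    position (ascending), then AP = mean over positives of the precision
    at that positive's rank.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise UndefinedMetricError("undefined metric: no positive labels")
    order = np.argsort(-scores, kind="stable")
    ranked = labels[order]
    cum_pos = np.cumsum(ranked)
    precision = cum_pos / np.arange(1, len(ranked) + 1)
    return float(precision[ranked == 1].sum() / n_pos)


def evaluate(
    W: np.ndarray,
    gold: EdgeSet,
    candidate_regulators: Sequence[int] | None = None,
) -> EvaluationResult:
    """Score weight matrix ``W`` (entry (j, i) = confidence of j -> i) against ``gold``.

    All ordered off-diagonal pairs are scored; pairs not listed in the
    gold standard count as negatives.  When a regulator list was used for
    inference, pass it so only those rows enter the ranking.
    """
    W = np.asarray(W, dtype=float)
    n = W.shape[0]
    if gold.n != n:
        raise ValueError(f"gold standard is over {gold.n} genes, matrix over {n}")
    if candidate_regulators is None:
        rows: Sequence[int] = range(n)
    else:
        rows = sorted(set(int(j) for j in candidate_regulators))
    positives = gold.positives
    scores, labels = [], []
    for j in rows:
        for i in range(n):
            if i == j:
                continue
            scores.append(W[j, i])
            labels.append(1 if (j, i) in positives else 0)
    scores_a = np.asarray(scores)
    labels_a = np.asarray(labels)
    return EvaluationResult(
        auroc=auroc(scores_a, labels_a),
        aupr=aupr(scores_a, labels_a),
        n_edges_scored=len(scores),
        n_positives=int(labels_a.sum()),
    )
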