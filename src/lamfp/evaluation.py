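"""Retrospective evaluation: test-subset construction and ranking metrics.

Test pairs are partitioned by training-set membership of their endpoints
into known-new (exactly one endpoint trained on), new-new (neither) and
known-known (both); "all" is the full test set. Metrics:

* AUC — area under the ROC curve, equivalently the normalized
  Mann-Whitney U statistic with ties counted one half.
* AUPR — area under the precision-recall curve in its average-precision
  (step-interpolated) form, which avoids the optimism of linear
  interpolation.
* MRR — mean over drugs of the reciprocal rank of the first true
  interaction in that drug's score-ordered candidate list. Drugs with no
  positive candidate are excluded from the mean (their reciprocal rank is
  undefined); the report carries the counts so the convention is visible.
* MAP@k — mean over drugs of average precision truncated at list depth k,
  normalized by min(k, number of positives).
* accuracy / specificity / sensitivity — from the 2x2 table at a fixed
  score threshold (default 0.5).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from lamfp.data_model import PredictionRecord, RetrospectiveSplit, ValidationError

SUBSET_ALL = "all"
SUBSET_KNOWN_NEW = "known_new"
SUBSET_NEW_NEW = "new_new"
SUBSET_KNOWN_KNOWN = "known_known"

DEFAULT_K_GRID = (1, 5, 10, 50, 100, 500)


def build_subsets(split: RetrospectiveSplit) -> dict[str, list[tuple[str, str, int]]]:
    """Partition the test pairs by endpoint membership in the train graph."""
    known = split.known_ids
    subsets: dict[str, list[tuple[str, str, int]]] = {
        SUBSET_ALL: [],
        SUBSET_KNOWN_NEW: [],
        SUBSET_NEW_NEW: [],
        SUBSET_KNOWN_KNOWN: [],
    }
    for a, b, label in split.test_pairs:
        subsets[SUBSET_ALL].append((a, b, label))
        n_known = (a in known) + (b in known)
        if n_known == 1:
            subsets[SUBSET_KNOWN_NEW].append((a, b, label))
        elif n_known == 0:
            subsets[SUBSET_NEW_NEW].append((a, b, label))
        else:
            subsets[SUBSET_KNOWN_KNOWN].append((a, b, label))
    return subsets


def _as_arrays(labels: Sequence[int], scores: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(labels, dtype=np.int64)
    s = np.asarray(scores, dtype=np.float64)
    if y.shape != s.shape or y.ndim != 1:
        raise ValidationError("labels and scores must be 1-D sequences of equal length")
    return y, s


def auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """ROC AUC; requires at least one positive and one negative."""
    y, s = _as_arrays(labels, scores)
    if y.min() == y.max():
        raise ValidationError("AUC is undefined for single-class labels")
    return float(roc_auc_score(y, s))


def aupr(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Average precision (step-interpolated area under the PR curve)."""
    y, s = _as_arrays(labels, scores)
    if y.sum() == 0:
        raise ValidationError("AUPR is undefined with no positive labels")
    return float(average_precision_score(y, s))


Rankings = Mapping[str, Sequence[int]]
"""Per-drug candidate lists: drug id -> binary labels ordered by descending score."""


def mrr(rankings: Rankings) -> float:
    """Mean reciprocal rank of the first positive per drug.

    Drugs with no positive in their list are excluded from the mean.
    """
    recip: list[float] = []
    for labels in rankings.values():
        for rank, lab in enumerate(labels, start=1):
            if lab == 1:
                recip.append(1.0 / rank)
                break
    if not recip:
        raise ValidationError("MRR is undefined: no drug has a positive candidate")
    return float(np.mean(recip))


def map_at_k(rankings: Rankings, k: int) -> float:
    """Mean over drugs of average precision truncated at depth k."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    aps: list[float] = []
    for labels in rankings.values():
        n_pos = sum(1 for lab in labels if lab == 1)
        if n_pos == 0:
            continue
        hits = 0
        precision_sum = 0.0
        for rank, lab in enumerate(labels[:k], start=1):
            if lab == 1:
                hits += 1
                precision_sum += hits / rank
        aps.append(precision_sum / min(k, n_pos))
    if not aps:
        raise ValidationError("MAP is undefined: no drug has a positive candidate")
    return float(np.mean(aps))


def confusion_metrics(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> tuple[float, float, float]:
    """(accuracy, specificity, sensitivity) at the given score threshold."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    y, s = _as_arrays(labels, scores)
    pred = (s >= threshold).astype(np.int64)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0:
        raise ValidationError("sensitivity is undefined with no positive labels")
    if n_neg == 0:
        raise ValidationError("specificity is undefined with no negative labels")
    accuracy = (tp + tn) / len(y)
    specificity = tn / n_neg
    sensitivity = tp / n_pos
    return accuracy, specificity, sensitivity


def rankings_from_predictions(
    pairs: Sequence[tuple[str, str, int]], scores: Mapping[tuple[str, str], float]
) -> dict[str, list[int]]:
    """Build per-drug ranked candidate lists from scored pairs.

    Every pair contributes to both endpoints' lists; within a drug's list
    the partners are ordered by descending score (ties by partner id).
    """
    per_drug: dict[str, list[tuple[float, str, int]]] = {}
    for a, b, label in pairs:
        score = scores[(a, b)]
        per_drug.setdefault(a, []).append((score, b, label))
        per_drug.setdefault(b, []).append((score, a, label))
    out: dict[str, list[int]] = {}
    for drug, items in per_drug.items():
        items.sort(key=lambda t: (-t[0], t[1]))
        out[drug] = [lab for _, _, lab in items]
    return out


@dataclass
class EvaluationReport:
    """Per-subset metric values plus the counts they were computed on."""

    metrics: dict[str, dict[str, float | None | dict[str, float | None]]]
    counts: dict[str, dict[str, int]]
    threshold: float
    k_grid: tuple[int, ...]
    notes: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "counts": self.counts,
            "threshold": self.threshold,
            "k_grid": list(self.k_grid),
            "notes": self.notes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def evaluate(
    predictions: Sequence[PredictionRecord],
    split: RetrospectiveSplit,
    k_grid: tuple[int, ...] = DEFAULT_K_GRID,
    threshold: float = 0.5,
) -> EvaluationReport:
    """Assemble the full per-subset metric report for a set of predictions.

    Metrics that are undefined on a subset (single-class labels, no
    positives) are reported as None rather than aborting the report;
    the standalone metric functions still raise in those cases.
    """
    score_map: dict[tuple[str, str], float] = {}
    for r in predictions:
        score_map[(r.drug_a, r.drug_b)] = r.score
        score_map[(r.drug_b, r.drug_a)] = r.score
    subsets = build_subsets(split)
    metrics: dict[str, dict] = {}
    counts: dict[str, dict[str, int]] = {}
    for name, pairs in subsets.items():
        pairs = [(a, b, lab) for a, b, lab in pairs if (a, b) in score_map]
        labels = [lab for _, _, lab in pairs]
        scores = [score_map[(a, b)] for a, b, _ in pairs]
        counts[name] = {
            "n_pairs": len(pairs),
            "n_positive": int(sum(labels)),
            "n_negative": len(labels) - int(sum(labels)),
        }
        entry: dict = {}
        if not pairs:
            metrics[name] = {
                "auc": None, "aupr": None, "mrr": None,
                "map_at_k": {str(k): None for k in k_grid},
                "accuracy": None, "specificity": None, "sensitivity": None,
            }
            continue
        try:
            entry["auc"] = auc(labels, scores)
        except ValidationError:
            entry["auc"] = None
        try:
            entry["aupr"] = aupr(labels, scores)
        except ValidationError:
            entry["aupr"] = None
        rankings = rankings_from_predictions(pairs, score_map)
        try:
            entry["mrr"] = mrr(rankings)
        except ValidationError:
            entry["mrr"] = None
        entry["map_at_k"] = {}
        for k in k_grid:
            try:
                entry["map_at_k"][str(k)] = map_at_k(rankings, k)
            except ValidationError:
                entry["map_at_k"][str(k)] = None
        try:
            acc, spec, sens = confusion_metrics(labels, scores, threshold)
            entry["accuracy"], entry["specificity"], entry["sensitivity"] = acc, spec, sens
        except ValidationError:
            entry["accuracy"] = entry["specificity"] = entry["sensitivity"] = None
        metrics[name] = entry
    return EvaluationReport(
        metrics=metrics,
        counts=counts,
        threshold=threshold,
        k_grid=tuple(k_grid),
        notes={
            "mrr_convention": "drugs with no positive candidate are excluded from MRR/MAP means"
        },
    )
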