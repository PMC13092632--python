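"""Evaluation metrics: retrieval P/R/F1, expansion accuracies, exact-match
link scoring, chance-corrected rater agreement and confusion matrices.

Conventions used throughout:

* all fractions live in [0, 1]; rendering as percentages rounds half-up to
  one decimal (``percent``);
* every 0/0 ratio is defined as 0 — an empty evaluation scores nothing;
* linking counts are micro-averaged across documents (the TP/FP/FN sets are
  pooled before the ratios are taken); a macro option is available.

Total accuracy composes the disambiguation chain end-to-end: an
abbreviation must first be found (recall) and then expanded to the right
sense (expansion accuracy), so ``total = recall × expansion_accuracy``.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Hashable, Mapping, Sequence

import numpy as np

__all__ = [
    "MetricsReport",
    "SurveyRatings",
    "percent",
    "prf",
    "expansion_metrics",
    "score_links",
    "cohens_kappa",
    "absolute_agreement",
    "confusion_matrix",
]


def percent(fraction: float, decimals: int = 1) -> float:
    """Render a fraction as a percentage, rounded half-up."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def _checked(*counts: int) -> None:
    for c in counts:
        if c < 0:
            raise ValueError(f"counts must be non-negative, got {c}")


def prf(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean; 0/0 ratios are 0."""
    _checked(tp, fp, fn)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def expansion_metrics(
    correct: int, incorrect: int, tp: int, fn: int
) -> tuple[float, float]:
    """Expansion accuracy and total accuracy of a disambiguation run.

    Expansion accuracy scores the attempted expansions; total accuracy
    multiplies in the detection recall so that missed abbreviations count
    against the end-to-end result.
    """
    _checked(correct, incorrect, tp, fn)
    expansion_accuracy = correct / (correct + incorrect) if correct + incorrect else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return expansion_accuracy, recall * expansion_accuracy


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    expansion_accuracy: float = 0.0
    total_accuracy: float = 0.0
    correct_expansions: int = 0
    incorrect_expansions: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "expansion_accuracy": self.expansion_accuracy,
            "total_accuracy": self.total_accuracy,
        }


def score_links(
    predicted: Mapping[str, Sequence[tuple[tuple[int, int], str]]],
    gold: Mapping[str, Sequence[tuple[tuple[int, int], str]]],
    average: str = "micro",
) -> MetricsReport:
    """Exact-match scoring of entity links against gold standoff.

    A prediction is a true positive only if both the exact character span
    and the concept identifier match a gold annotation in the same
    document; overlapping-but-inexact spans are a false positive *and* a
    false negative.  ``average="micro"`` pools counts over documents;
    ``"macro"`` averages per-document P/R/F1.
    """
    if average not in ("micro", "macro"):
        raise ValueError("average must be 'micro' or 'macro'")
    doc_ids = sorted(set(predicted) | set(gold))
    totals = np.zeros(3, dtype=int)  # tp, fp, fn
    per_doc = []
    for doc_id in doc_ids:
        pred_set = {(tuple(span), cid) for span, cid in predicted.get(doc_id, [])}
        gold_set = {(tuple(span), cid) for span, cid in gold.get(doc_id, [])}
        tp = len(pred_set & gold_set)
        fp = len(pred_set - gold_set)
        fn = len(gold_set - pred_set)
        totals += (tp, fp, fn)
        per_doc.append(prf(tp, fp, fn))
    tp, fp, fn = (int(x) for x in totals)
    if average == "micro" or not per_doc:
        precision, recall, f1 = prf(tp, fp, fn)
    else:
        precision, recall, f1 = (float(np.mean([d[i] for d in per_doc])) for i in range(3))
    return MetricsReport(precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# rater agreement


@dataclass(frozen=True)
class SurveyRatings:
    """Ratings of survey items by multiple raters on a categorical scale.

    ``items`` maps an item id to the tuple of ratings, one per rater, in a
    fixed rater order (e.g. the 3-point scale no/partial/complete match).
    """

    items: Mapping[Hashable, tuple[Hashable, ...]]

    def __post_init__(self) -> None:
        sizes = {len(r) for r in self.items.values()}
        if len(sizes) > 1:
            raise ValueError("every item must have the same number of raters")

    def rater_column(self, rater: int) -> list[Hashable]:
        return [self.items[k][rater] for k in sorted(self.items, key=str)]


def cohens_kappa(rater_a: Sequence[Hashable], rater_b: Sequence[Hashable]) -> float:
    """Chance-corrected pairwise agreement, κ = (p_o − p_e) / (1 − p_e).

    Expected agreement p_e comes from the product of the two raters'
    marginal category frequencies.  Degenerate perfect case (p_e = 1,
    both raters constant and equal) returns 1.  Range is [−1, 1]; heavily
    imbalanced marginals can push κ far below the raw agreement — the
    "kappa paradox".
    """
    if len(rater_a) != len(rater_b):
        raise ValueError("rating sequences must have equal length")
    n = len(rater_a)
    if n == 0:
        raise ValueError("at least one rated item is required")
    categories = sorted(set(rater_a) | set(rater_b), key=str)
    p_o = sum(a == b for a, b in zip(rater_a, rater_b)) / n
    p_e = sum(
        (sum(a == c for a in rater_a) / n) * (sum(b == c for b in rater_b) / n)
        for c in categories
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1.0 - p_e)


def absolute_agreement(ratings: SurveyRatings) -> float:
    """Share of items on which every rater chose the same category."""
    if not ratings.items:
        raise ValueError("at least one rated item is required")
    unanimous = sum(1 for r in ratings.items.values() if len(set(r)) == 1)
    return unanimous / len(ratings.items)


# ---------------------------------------------------------------------------
# classification


def confusion_matrix(
    true_labels: Sequence[Hashable],
    predicted_labels: Sequence[Hashable],
    class_order: Sequence[Hashable],
) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized confusion matrix plus raw counts.

    Rows are actual classes, columns predicted, both in ``class_order``.
    Row normalization divides by the row sum (zero rows stay zero), giving
    per-class accuracy on the diagonal.
    """
    index = {c: i for i, c in enumerate(class_order)}
    for label in list(true_labels) + list(predicted_labels):
        if label not in index:
            raise ValueError(f"label {label!r} not in class order {list(class_order)}")
    counts = np.zeros((len(class_order), len(class_order)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts[index[t], index[p]] += 1
    row_sums = counts.sum(axis=1, keepdims=True)
    normalized = np.divide(
        counts, row_sums, out=np.zeros_like(counts, dtype=float), where=row_sums > 0
    )
    return normalized, counts
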