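"""Heart-failure classification from linked concepts and EHR features.

Each patient is represented by the concatenation of

* a TF-IDF-weighted bag of terminology concepts — every linked concept
  contributes itself plus *all* of its is-a ancestors, so rare specific
  findings generalize to the broader clinical categories above them; and
* a normalized EHR vector — numeric features z-scored, categorical
  features one-hot encoded, missing values imputed (median / explicit
  "missing" level).

The four diagnosis classes are no heart failure plus the three subtypes
defined by left-ventricular ejection fraction: reduced (HFrEF), mildly
reduced (HFmrEF) and preserved (HFpEF).  The classifier is a linear model
trained with hinge loss (an SVM fitted by stochastic gradient descent) in
a one-vs-rest scheme, with balanced class weights against the cohort's
class imbalance.  Evaluation is stratified k-fold cross-validation; all
fit-time state (TF-IDF vocabulary and idf values, normalization statistics)
is learned on the training folds only, so concepts unseen in training
simply contribute nothing for test patients.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.linear_model import SGDClassifier
from sklearn.model_selection import StratifiedKFold

from .metrics import confusion_matrix as _confusion
from .terminology import TerminologyIndex

__all__ = [
    "CLASSES",
    "PatientRecord",
    "TrainConfig",
    "expand_with_ancestors",
    "ConceptTfidfVectorizer",
    "EhrNormalizer",
    "train",
    "decision_scores",
    "cross_validate",
]

CLASSES = ("NoHF", "HFrEF", "HFmrEF", "HFpEF")


@dataclass
class PatientRecord:
    patient_id: str
    concept_ids: list[str]
    ehr: dict[str, object]
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")


@dataclass
class TrainConfig:
    loss: str = "hinge"
    class_weight: str = "balanced"
    random_seed: int = 2026
    folds: int = 5
    stratified: bool = True


def expand_with_ancestors(
    concept_ids: Iterable[str], index: TerminologyIndex
) -> Counter:
    """Each concept occurrence contributes itself and every is-a ancestor.

    Concepts unknown to the index (e.g. links into a terminology without a
    hierarchy) are kept as themselves with no expansion.
    """
    bag: Counter = Counter()
    for cid in concept_ids:
        bag[cid] += 1
        if cid in index.concepts:
            for anc in index.ancestors(cid):
                bag[anc] += 1
    return bag


class ConceptTfidfVectorizer:
    """TF-IDF weighting over per-patient concept bags.

    Vocabulary is the set of concepts seen during ``fit`` (training folds
    only); weighting is the conventional smoothed variant,
    idf = ln((1 + N) / (1 + df)) + 1, with L2-normalized rows.  Concepts
    outside the vocabulary are silently ignored at transform time, which is
    what makes test-fold vectors sparse.
    """

    def __init__(self) -> None:
        self.vocabulary_: dict[str, int] = {}
        self._tfidf = TfidfTransformer(smooth_idf=True, norm="l2")

    def _counts(self, bags: Sequence[Mapping[str, int]]) -> sp.csr_matrix:
        rows, cols, data = [], [], []
        for i, bag in enumerate(bags):
            for cid, count in bag.items():
                j = self.vocabulary_.get(cid)
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    data.append(count)
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(len(bags), len(self.vocabulary_))
        )

    def fit(self, bags: Sequence[Mapping[str, int]]) -> "ConceptTfidfVectorizer":
        if not bags:
            raise ValueError("cannot fit TF-IDF on an empty corpus")
        vocab = sorted({cid for bag in bags for cid in bag})
        self.vocabulary_ = {cid: j for j, cid in enumerate(vocab)}
        self._tfidf.fit(self._counts(bags))
        return self

    def transform(self, bags: Sequence[Mapping[str, int]]) -> sp.csr_matrix:
        if not self.vocabulary_:
            raise RuntimeError("vectorizer is not fitted")
        return self._tfidf.transform(self._counts(bags))

    @property
    def idf_(self) -> np.ndarray:
        return self._tfidf.idf_


class EhrNormalizer:
    """Training-fold normalization of tabular EHR features.

    Feature typing is inferred at fit time: a feature whose observed
    non-missing values are all numeric is z-scored (zero-variance features
    get a unit divisor) with missing values imputed to the training median;
    all other features are one-hot encoded with an explicit ``"missing"``
    level.  The feature schema is frozen at fit time — a record mentioning
    an unknown feature at transform time is a schema error.
    """

    def __init__(self) -> None:
        self.numeric_stats_: dict[str, tuple[float, float, float]] = {}  # mean, std, median
        self.categorical_levels_: dict[str, list[str]] = {}
        self.feature_names_: list[str] = []

    @staticmethod
    def _is_missing(v: object) -> bool:
        return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""

    def fit(self, records: Sequence[Mapping[str, object]]) -> "EhrNormalizer":
        keys = sorted({k for r in records for k in r})
        for key in keys:
            observed = [r.get(key) for r in records if not self._is_missing(r.get(key))]
            numeric = bool(observed) and all(
                isinstance(v, (int, float)) and not isinstance(v, bool) for v in observed
            )
            if numeric:
                arr = np.asarray(observed, dtype=float)
                std = float(arr.std())
                self.numeric_stats_[key] = (
                    float(arr.mean()),
                    std if std > 0 else 1.0,
                    float(np.median(arr)),
                )
            else:
                levels = sorted({str(v) for v in observed}) + ["missing"]
                self.categorical_levels_[key] = levels
        self.feature_names_ = []
        for key in keys:
            if key in self.numeric_stats_:
                self.feature_names_.append(key)
            else:
                self.feature_names_.extend(
                    f"{key}={lvl}" for lvl in self.categorical_levels_[key]
                )
        return self

    def transform(self, records: Sequence[Mapping[str, object]]) -> np.ndarray:
        if not self.feature_names_:
            raise RuntimeError("normalizer is not fitted")
        known = set(self.numeric_stats_) | set(self.categorical_levels_)
        out = np.zeros((len(records), len(self.feature_names_)))
        col_of = {name: j for j, name in enumerate(self.feature_names_)}
        for i, record in enumerate(records):
            unknown = set(record) - known
            if unknown:
                raise KeyError(f"features outside the fitted schema: {sorted(unknown)}")
            for key, (mean, std, median) in self.numeric_stats_.items():
                v = record.get(key)
                x = median if self._is_missing(v) else float(v)
                out[i, col_of[key]] = (x - mean) / std
            for key, levels in self.categorical_levels_.items():
                v = record.get(key)
                level = "missing" if self._is_missing(v) else str(v)
                if level not in levels:
                    level = "missing"  # unseen category at test time
                out[i, col_of[f"{key}={level}"]] = 1.0
        return out


def train(
    vectors: sp.spmatrix | np.ndarray,
    labels: Sequence[str],
    config: TrainConfig | None = None,
) -> SGDClassifier:
    """Fit the hinge-loss linear classifier (one-vs-rest, balanced weights)."""
    config = config or TrainConfig()
    if len(set(labels)) < 2:
        raise ValueError("training requires at least two classes")
    model = SGDClassifier(
        loss=config.loss,
        class_weight=config.class_weight,
        random_state=config.random_seed,
    )
    model.fit(vectors, list(labels))
    return model


def decision_scores(model: SGDClassifier, vectors) -> np.ndarray:
    """Softmax over the per-class decision values.

    Hinge-loss models produce margins, not probabilities; this softmax is a
    monotone calibration for ranking/report purposes only and must not be
    read as a calibrated probability.
    """
    margins = model.decision_function(vectors)
    if margins.ndim == 1:
        # binary models emit one margin; positive favors classes_[1]
        margins = np.column_stack([-margins, margins])
    shifted = margins - margins.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


def _patient_matrix(
    records: Sequence[PatientRecord],
    index: TerminologyIndex,
    feature_mode: str,
    vectorizer: ConceptTfidfVectorizer | None,
    normalizer: EhrNormalizer | None,
):
    parts = []
    if feature_mode in ("concepts_only", "combined"):
        bags = [expand_with_ancestors(r.concept_ids, index) for r in records]
        parts.append(vectorizer.transform(bags))
    if feature_mode in ("ehr_only", "combined"):
        parts.append(sp.csr_matrix(normalizer.transform([r.ehr for r in records])))
    return sp.hstack(parts).tocsr() if len(parts) > 1 else parts[0]


def cross_validate(
    records: Sequence[PatientRecord],
    index: TerminologyIndex,
    config: TrainConfig | None = None,
    feature_mode: str = "combined",
) -> dict:
    """Stratified k-fold cross-validation with leakage-free fitting.

    TF-IDF (vocabulary + idf) and EHR normalization are refit on every
    training fold; test-fold predictions are pooled across folds and scored
    with support-weighted and macro precision/recall/F1 plus the
    row-normalized confusion matrix over the four diagnosis classes.
    """
    if feature_mode not in ("ehr_only", "concepts_only", "combined"):
        raise ValueError(f"unknown feature mode: {feature_mode}")
    config = config or TrainConfig()
    labels = np.array([r.label for r in records])
    class_counts = Counter(labels)
    too_small = [c for c, n in class_counts.items() if n < config.folds]
    if too_small:
        raise ValueError(
            f"stratified {config.folds}-fold CV impossible: classes {too_small} "
            f"have fewer than {config.folds} members"
        )
    splitter = StratifiedKFold(
        n_splits=config.folds, shuffle=True, random_state=config.random_seed
    )
    y_true: list[str] = []
    y_pred: list[str] = []
    fold_assignment = np.empty(len(records), dtype=int)
    for fold, (train_idx, test_idx) in enumerate(splitter.split(np.zeros(len(records)), labels)):
        fold_assignment[test_idx] = fold
        train_records = [records[i] for i in train_idx]
        test_records = [records[i] for i in test_idx]
        vectorizer = normalizer = None
        if feature_mode in ("concepts_only", "combined"):
            vectorizer = ConceptTfidfVectorizer().fit(
                [expand_with_ancestors(r.concept_ids, index) for r in train_records]
            )
        if feature_mode in ("ehr_only", "combined"):
            normalizer = EhrNormalizer().fit([r.ehr for r in train_records])
        x_train = _patient_matrix(train_records, index, feature_mode, vectorizer, normalizer)
        x_test = _patient_matrix(test_records, index, feature_mode, vectorizer, normalizer)
        model = train(x_train, [r.label for r in train_records], config)
        y_true.extend(r.label for r in test_records)
        y_pred.extend(model.predict(x_test))

    present = [c for c in CLASSES if c in set(y_true) | set(y_pred)]
    per_class = {}
    for c in present:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[c] = {
            "precision": precision, "recall": recall, "f1": f1,
            "support": sum(1 for t in y_true if t == c),
        }
    support = np.array([per_class[c]["support"] for c in present], dtype=float)
    weights = support / support.sum()

    def _avg(metric: str, w) -> float:
        values = np.array([per_class[c][metric] for c in present])
        return float(np.average(values, weights=w))

    normalized, counts = _confusion(y_true, y_pred, CLASSES)
    return {
        "feature_mode": feature_mode,
        "precision": _avg("precision", weights),
        "recall": _avg("recall", weights),
        "f1": _avg("f1", weights),
        "macro_precision": _avg("precision", None),
        "macro_recall": _avg("recall", None),
        "macro_f1": _avg("f1", None),
        "per_class": per_class,
        "confusion_normalized": normalized,
        "confusion_counts": counts,
        "fold_assignment": fold_assignment,
        "y_true": y_true,
        "y_pred": y_pred,
    }
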