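"""Cross-validation, classification metrics and Table-style reporting.

Metrics follow the usual conventions for balanced multi-class problems:
accuracy plus macro-averaged precision, recall and F1 (averaged over the
classes present in the truth; a class never predicted contributes
precision 0). Reports carry per-fold values and their mean and sample
standard deviation, all on a percent scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

METRIC_NAMES = ("accuracy", "precision", "recall", "f1")


@dataclass(frozen=True, slots=True)
class FoldAssignment:
    """A stratified partition of samples into folds."""

    n_folds: int
    assignment: np.ndarray  # per-sample fold index in [0, n_folds)

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != fold)


@dataclass
class MetricsReport:
    """Per-fold metric values (percent) with across-fold mean and std."""

    per_fold: list[dict[str, float]]

    def mean(self, metric: str) -> float:
        return float(np.mean([f[metric] for f in self.per_fold]))

    def std(self, metric: str) -> float:
        vals = [f[metric] for f in self.per_fold]
        return float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0

    @property
    def n_folds(self) -> int:
        return len(self.per_fold)

    def summary(self) -> dict[str, dict[str, float]]:
        return {m: {"mean": self.mean(m), "std": self.std(m)} for m in METRIC_NAMES}

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.per_fold)
        df.index.name = "fold"
        return df

    def to_json(self) -> str:
        return json.dumps({"per_fold": self.per_fold})

    @staticmethod
    def from_json(text: str) -> "MetricsReport":
        return MetricsReport(per_fold=json.loads(text)["per_fold"])


def make_folds(labels: Sequence, n_folds: int = 10, seed: int = 0,
               groups: Sequence | None = None) -> FoldAssignment:
    """Seeded stratified fold assignment.

    Fold sizes differ by at most one, as do per-class counts per fold. A
    class with fewer members than folds triggers a warning (some folds
    then miss it), not an error. With *groups* (e.g. source-reference
    ids), all samples of a group land in the same fold — the leakage-safe
    alternative to read-level assignment — at the cost of the exact
    size-balance guarantees.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if n_folds > n:
        raise ValueError(f"n_folds={n_folds} exceeds sample count {n}")
    if groups is None:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = skf.split(np.zeros((n, 1)), labels)
    else:
        sgkf = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = sgkf.split(np.zeros((n, 1)), labels, groups=np.asarray(groups))
    assignment = np.empty(n, dtype=np.int64)
    for fold, (_, test_idx) in enumerate(splits):
        assignment[test_idx] = fold
    return FoldAssignment(n_folds=n_folds, assignment=assignment)


def compute_metrics(y_true: Sequence, y_pred: Sequence, average: str = "macro") -> dict[str, float]:
    """Accuracy and averaged precision/recall/F1 in percent.

    Averaging is over the classes present in ``y_true``; ``average`` may
    be ``"macro"`` (default) or ``"weighted"``.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty prediction set")
    classes = np.unique(y_true)
    p, r, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=classes, average=average, zero_division=0
    )
    return {
        "accuracy": 100.0 * float(accuracy_score(y_true, y_pred)),
        "precision": 100.0 * float(p),
        "recall": 100.0 * float(r),
        "f1": 100.0 * float(f1),
    }


def cross_validate(
    X,
    labels: Sequence,
    classifier_factory: Callable[[], object],
    n_folds: int = 10,
    seed: int = 0,
    average: str = "macro",
    groups: Sequence | None = None,
) -> MetricsReport:
    """Stratified k-fold evaluation of a classifier.

    ``classifier_factory`` returns a fresh estimator with ``fit(X, y)``
    and ``predict(X)``; a new one is fitted per fold on the training
    portion only, so anything the estimator derives from data (label
    dictionary, fitted normalisation) never sees the held-out fold. ``X``
    may be a numpy matrix or a sequence (e.g. raw read strings for the
    naive Bayes baseline). *groups* keeps all reads of one reference in
    one fold (see :func:`make_folds`).
    """
    labels = np.asarray(labels)
    folds = make_folds(labels, n_folds=n_folds, seed=seed, groups=groups)
    is_matrix = isinstance(X, np.ndarray)

    def take(idx):
        return X[idx] if is_matrix else [X[i] for i in idx]

    per_fold = []
    for fold in range(n_folds):
        tr, te = folds.train_indices(fold), folds.test_indices(fold)
        clf = classifier_factory()
        clf.fit(take(tr), labels[tr])
        y_pred = clf.predict(take(te))
        per_fold.append(compute_metrics(labels[te], y_pred, average=average))
    return MetricsReport(per_fold=per_fold)


def cross_technology_eval(
    X_train,
    labels_train: Sequence,
    X_test,
    labels_test: Sequence,
    classifier_factory: Callable[[], object],
    average: str = "macro",
) -> MetricsReport:
    """Train on one technology's reads, test on the other's (no folding).

    The report contains a single "fold". Feature dimensionality must
    match between the two sides.
    """
    if isinstance(X_train, np.ndarray) and isinstance(X_test, np.ndarray):
        if X_train.shape[1] != X_test.shape[1]:
            raise ValueError(
                f"feature dimension mismatch: train {X_train.shape[1]} vs test {X_test.shape[1]}"
            )
    clf = classifier_factory()
    clf.fit(X_train, np.asarray(labels_train))
    y_pred = clf.predict(X_test)
    return MetricsReport(per_fold=[compute_metrics(np.asarray(labels_test), y_pred,
                                                   average=average)])


def report_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble per-configuration summaries (rank x algorithm x k) into a
    flat table with mean% and std per metric."""
    records = []
    for row in rows:
        rep: MetricsReport = row["report"]
        rec = {k: v for k, v in row.items() if k != "report"}
        for m in METRIC_NAMES:
            rec[f"{m}_mean"] = rep.mean(m)
            rec[f"{m}_std"] = rep.std(m)
        records.append(rec)
    return pd.DataFrame(records)
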