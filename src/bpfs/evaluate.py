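"""Classification evaluation harness.

Protocol: a stratified 80/20 split of the samples, gene selection fit on the
training rows only, a linear-kernel SVM trained on the selected genes, and
six test-set metrics — accuracy, sensitivity, specificity, precision,
balanced accuracy and F1 — with the cancer class as positive.

Gene selection is unsupervised, but it still runs strictly on the training
rows so that the test half informs neither the gene set nor the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .matrix import ExpressionMatrix, Orientation
from .select import BPFSConfig, SelectionResult, run_bpfs

POSITIVE = 1  #: label code for the cancer class
NEGATIVE = 0  #: label code for the normal class


@dataclass(frozen=True)
class LabelVector:
    """Binary per-sample labels, aligned to a matrix by sample ID."""

    sample_ids: tuple[str, ...]
    labels: np.ndarray  # int array of 0 (normal) / 1 (cancer)

    def __post_init__(self) -> None:
        ids = tuple(str(s) for s in self.sample_ids)
        lab = np.asarray(self.labels, dtype=int)
        if len(ids) != lab.size:
            raise ValueError("sample_ids and labels length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample IDs in labels")
        if not np.all(np.isin(lab, [NEGATIVE, POSITIVE])):
            raise ValueError("labels must be binary 0/1")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "labels", lab)

    def aligned_to(self, X: ExpressionMatrix) -> np.ndarray:
        """Label array reordered to the matrix's sample order (by ID)."""
        if X.orientation is not Orientation.SAMPLES_BY_GENES:
            raise ValueError("expected a samples_by_genes matrix")
        lookup = dict(zip(self.sample_ids, self.labels))
        missing = [s for s in X.row_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples without labels: {missing[:10]}")
        return np.array([lookup[s] for s in X.row_ids], dtype=int)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts with cancer as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v}")

    @property
    def p(self) -> int:
        """Total positive (cancer) cases."""
        return self.tp + self.fn

    @property
    def n(self) -> int:
        """Total negative (normal) cases."""
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """The six evaluation metrics, each in [0, 1].

    ``warnings`` lists metrics whose denominator was zero and which were
    reported as 0 instead of raising, so degenerate splits stay visible
    without aborting batch runs.
    """

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float
    f1: float
    warnings: tuple[str, ...] = ()

    def as_dict(self, ndigits: int | None = None) -> dict[str, float]:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "balanced_accuracy": self.balanced_accuracy,
            "f1": self.f1,
        }
        if ndigits is not None:
            d = {k: round(v, ndigits) for k, v in d.items()}
        return d


@dataclass(frozen=True)
class EvaluationResult:
    metrics: MetricsReport
    confusion: ConfusionCounts
    selection: SelectionResult
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]


def split_train_test(
    X: ExpressionMatrix,
    y: LabelVector,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[ExpressionMatrix, np.ndarray, ExpressionMatrix, np.ndarray]:
    """Stratified, seeded train/test split over samples (matrix rows).

    The train size is ``floor(train_fraction * n_samples)`` with class
    proportions preserved, so a small normal class cannot be emptied out of
    either half.  Returns ``(X_train, y_train, X_test, y_test)``.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    labels = y.aligned_to(X)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("each class needs >=2 members to stratify")
    idx = np.arange(X.n_rows)
    train_idx, test_idx = train_test_split(
        idx,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
        shuffle=True,
    )
    train_idx = np.sort(train_idx)
    test_idx = np.sort(test_idx)
    X_train = X.subset_rows([X.row_ids[i] for i in train_idx])
    X_test = X.subset_rows([X.row_ids[i] for i in test_idx])
    return X_train, labels[train_idx], X_test, labels[test_idx]


def compute_confusion(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionCounts:
    """Tally TP/FP/TN/FN with class 1 (cancer) positive."""
    t = np.asarray(y_true, dtype=int)
    p = np.asarray(y_pred, dtype=int)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    return ConfusionCounts(
        tp=int(np.sum((t == POSITIVE) & (p == POSITIVE))),
        fp=int(np.sum((t == NEGATIVE) & (p == POSITIVE))),
        tn=int(np.sum((t == NEGATIVE) & (p == NEGATIVE))),
        fn=int(np.sum((t == POSITIVE) & (p == NEGATIVE))),
    )


def _ratio(num: float, den: float, name: str, warn: list[str]) -> float:
    if den == 0:
        warn.append(name)
        return 0.0
    return num / den


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Derive the six metrics from confusion counts.

    accuracy = (TP+TN)/(P+N); sensitivity = TP/P; specificity = TN/N;
    precision = TP/(TP+FP); balanced accuracy = (sensitivity+specificity)/2;
    F1 = 2TP/(2TP+FP+FN).  A zero denominator yields 0 plus a warning flag.
    """
    if c.total == 0:
        raise ValueError("confusion counts are all zero")
    warn: list[str] = []
    sens = _ratio(c.tp, c.p, "sensitivity", warn)
    spec = _ratio(c.tn, c.n, "specificity", warn)
    return MetricsReport(
        accuracy=(c.tp + c.tn) / c.total,
        sensitivity=sens,
        specificity=spec,
        precision=_ratio(c.tp, c.tp + c.fp, "precision", warn),
        balanced_accuracy=(sens + spec) / 2,
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn, "f1", warn),
        warnings=tuple(warn),
    )


def make_classifier(settings: Mapping[str, object] | None = None):
    """Default classifier: standardize features, then linear-kernel SVC (C=1).

    Per-gene standardization is fit on the training data only.  It leaves
    the decision problem equivalent but keeps the SVM solver well
    conditioned on TPM scales, whose dynamic range spans orders of
    magnitude.  ``settings`` override the SVC parameters (e.g. ``C``,
    ``kernel``).
    """
    params: dict = {"kernel": "linear", "C": 1.0}
    params.update(settings or {})
    return make_pipeline(StandardScaler(), SVC(**params))


def evaluate_selection(
    X: ExpressionMatrix,
    y: LabelVector,
    config: BPFSConfig | None = None,
    classifier_settings: Mapping[str, object] | None = None,
    train_fraction: float = 0.8,
    seed: int = 0,
    phase1_only: bool = False,
) -> EvaluationResult:
    """End-to-end evaluation of the selection on one stratified split.

    Gene selection is fit on the training rows only; the selected gene
    columns filter both halves; the classifier trains on the filtered
    training data and is scored on the held-out test half.
    """
    X_train, y_train, X_test, y_test = split_train_test(
        X, y, train_fraction=train_fraction, seed=seed
    )
    _, selection = run_bpfs(X_train, config, phase1_only=phase1_only)
    genes = selection.final_genes
    clf = make_classifier(classifier_settings)
    clf.fit(X_train.subset_columns(genes).values, y_train)
    y_pred = clf.predict(X_test.subset_columns(genes).values)
    confusion = compute_confusion(y_test, y_pred)
    return EvaluationResult(
        metrics=compute_metrics(confusion),
        confusion=confusion,
        selection=selection,
        train_ids=X_train.row_ids,
        test_ids=X_test.row_ids,
    )
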