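"""Diagnostic-test metrics and the stratified k-fold evaluation protocol.

A binary screening test is summarized by its confusion matrix and three
indicators, reported as percentages:

    sensitivity (TPR) = 100 * tp / (tp + fn)   -- truly diseased found
    specificity (TNR) = 100 * tn / (tn + fp)   -- truly healthy found
    accuracy          = 100 * (tp + tn) / total

An undefined ratio (zero denominator) is reported as NaN, never as a
silent zero.  Printed reports round to two decimals; full precision is
retained internally.

Generalization to unknown patterns is assessed by k-fold cross-validation
(k=10 by default).  Folds are stratified: a continuous round-robin deal of
the class-grouped, seed-shuffled indices guarantees both that total fold
sizes differ by at most one and that per-class counts per fold differ by
at most one.  For each fold the translation is fitted and the memory
learned on the training portion only; the held-out portion is classified
with the training offsets.  The headline aggregate is the pooled (summed)
confusion matrix across folds; the mean of per-fold metrics is reported
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import delta_am
from .dataio import FundamentalSet, validate_schema
from .delta_am import MemoryConfig
from .errors import SchemaError, ValidationError
from .preprocessing import apply_to_patterns, apply_translation, fit_translation


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_class: str = "presence"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValidationError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.fn + other.fn,
            self.tn + other.tn,
            self.fp + other.fp,
            self.positive_class,
        )


@dataclass(frozen=True)
class MetricsReport:
    """The three indicators as percentages in [0, 100] (NaN if undefined)."""

    sensitivity: float
    specificity: float
    accuracy: float

    def rounded(self) -> "MetricsReport":
        """Two-decimal presentation copy (printed-report convention)."""
        r = lambda v: v if math.isnan(v) else round(v, 2)
        return MetricsReport(r(self.sensitivity), r(self.specificity), r(self.accuracy))

    def as_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def confusion(
    true_labels: Sequence,
    predicted_labels: Sequence,
    positive_class,
    reject_marker=None,
) -> ConfusionMatrix:
    """Tabulate a binary confusion matrix.

    A predicted value equal to ``reject_marker`` (None by default) counts
    as an error against the true class: a rejected positive is a false
    negative, a rejected negative a false positive.
    """
    true_labels = list(true_labels)
    predicted_labels = list(predicted_labels)
    if len(true_labels) == 0:
        raise ValidationError("empty label sequences")
    if len(true_labels) != len(predicted_labels):
        raise ValidationError(
            f"length mismatch: {len(true_labels)} true vs {len(predicted_labels)} predicted"
        )
    seen = set(true_labels) | {p for p in predicted_labels if p != reject_marker}
    if len(seen - {positive_class}) > 1:
        raise ValidationError(f"more than two classes present: {sorted(map(str, seen))}")
    tp = fn = tn = fp = 0
    for t, p in zip(true_labels, predicted_labels):
        if t == positive_class:
            if p == t:
                tp += 1
            else:
                fn += 1  # includes rejects of true positives
        else:
            if p == t:
                tn += 1
            else:
                fp += 1  # includes rejects of true negatives
    return ConfusionMatrix(tp, fn, tn, fp, positive_class=str(positive_class))


def metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Sensitivity, specificity and accuracy from confusion-matrix counts."""
    sens = 100.0 * cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) > 0 else math.nan
    spec = 100.0 * cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) > 0 else math.nan
    acc = 100.0 * (cm.tp + cm.tn) / cm.total if cm.total > 0 else math.nan
    return MetricsReport(sens, spec, acc)


@dataclass(frozen=True)
class FoldPlan:
    """Fold index per association; every pattern belongs to exactly one fold."""

    k: int
    assignments: np.ndarray
    seed: int
    stratified: bool

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def stratified_folds(
    fs: FundamentalSet, k: int = 10, seed: int = 0, stratified: bool = True
) -> FoldPlan:
    """Deterministic (seeded) fold assignment.

    Stratified mode shuffles indices within each class, then deals the
    class blocks round-robin with a *continuous* fold counter, so fold
    sizes differ by at most 1 overall and by at most 1 within each class.
    Unstratified mode deals a single shuffled permutation the same way.
    """
    if k < 2:
        raise SchemaError("k must be at least 2")
    if k > fs.p:
        raise SchemaError(f"k={k} exceeds the number of patterns p={fs.p}")
    rng = np.random.default_rng(seed)
    assignments = np.empty(fs.p, dtype=int)
    if stratified:
        counts = np.bincount(fs.y, minlength=fs.n_classes)
        short = [fs.class_names[c] for c in range(fs.n_classes) if counts[c] < k]
        if short:
            raise SchemaError(
                f"classes {short} have fewer than k={k} members; "
                "use stratified=False to fall back to plain k-fold"
            )
        counter = int(rng.integers(k))  # random starting fold, then continuous deal
        for c in range(fs.n_classes):
            idx = np.flatnonzero(fs.y == c)
            rng.shuffle(idx)
            for i in idx:
                assignments[i] = counter % k
                counter += 1
    else:
        perm = rng.permutation(fs.p)
        start = int(rng.integers(k))
        for pos, i in enumerate(perm):
            assignments[i] = (start + pos) % k
    return FoldPlan(k=k, assignments=assignments, seed=seed, stratified=stratified)


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation reports."""

    fold_plan: FoldPlan
    fold_matrices: list[ConfusionMatrix]
    fold_reports: list[MetricsReport]
    pooled_matrix: ConfusionMatrix
    pooled: MetricsReport
    mean_of_folds: MetricsReport
    positive_class: str

    def as_dict(self) -> dict:
        return {
            "k": self.fold_plan.k,
            "seed": self.fold_plan.seed,
            "stratified": self.fold_plan.stratified,
            "positive_class": self.positive_class,
            "pooled_confusion": {
                "tp": self.pooled_matrix.tp,
                "fn": self.pooled_matrix.fn,
                "tn": self.pooled_matrix.tn,
                "fp": self.pooled_matrix.fp,
            },
            "pooled": self.pooled.rounded().as_dict(),
            "mean_of_folds": self.mean_of_folds.rounded().as_dict(),
            "folds": [r.rounded().as_dict() for r in self.fold_reports],
        }

    def as_text(self) -> str:
        lines = [
            f"{'':12s}{'Sensitivity':>12s}{'Specificity':>12s}{'Accuracy':>10s}",
        ]

        def row(name: str, rep: MetricsReport) -> str:
            fmt = lambda v: "   n/a" if math.isnan(v) else f"{v:.2f}"
            return f"{name:12s}{fmt(rep.sensitivity):>12s}{fmt(rep.specificity):>12s}{fmt(rep.accuracy):>10s}"

        for i, rep in enumerate(self.fold_reports):
            lines.append(row(f"fold {i + 1}", rep))
        lines.append(row("pooled", self.pooled))
        lines.append(row("mean", self.mean_of_folds))
        return "\n".join(lines)


def _mean_of_folds(reports: list[MetricsReport]) -> MetricsReport:
    def nanmean(vals: list[float]) -> float:
        vals = [v for v in vals if not math.isnan(v)]
        return sum(vals) / len(vals) if vals else math.nan

    return MetricsReport(
        nanmean([r.sensitivity for r in reports]),
        nanmean([r.specificity for r in reports]),
        nanmean([r.accuracy for r in reports]),
    )


def cross_validate(
    fs: FundamentalSet,
    k: int = 10,
    seed: int = 0,
    config: MemoryConfig | None = None,
    translation_mode: str = "mean",
    custom_offsets: Sequence[float] | None = None,
    positive_class: str = "presence",
    stratified: bool = True,
) -> CVResult:
    """k-fold cross-validation of the full translate-then-learn pipeline.

    For each fold the translation is fitted and the memory learned on the
    training portion only; held-out patterns are translated with the
    training offsets and classified.  Fully reproducible from
    (fs, k, seed, config): the model itself has no randomness, so two
    seeds can differ only through fold assignment.
    """
    problems = validate_schema(fs, for_learning=True)
    if problems:
        raise SchemaError("invalid fundamental set: " + "; ".join(problems))
    if positive_class not in fs.class_names:
        raise SchemaError(
            f"positive class {positive_class!r} not among classes {fs.class_names}"
        )
    plan = stratified_folds(fs, k=k, seed=seed, stratified=stratified)
    fold_matrices: list[ConfusionMatrix] = []
    fold_reports: list[MetricsReport] = []
    for fold in range(k):
        try:
            train = fs.subset(plan.train_indices(fold))
            test_idx = plan.test_indices(fold)
            transform = fit_translation(train, mode=translation_mode, custom_offsets=custom_offsets)
            mem = delta_am.learn(apply_translation(transform, train), config)
            X_test = apply_to_patterns(transform, fs.X[test_idx])
            preds = [
                res.label.name if res.label is not None else None
                for res in delta_am.classify_many(mem, X_test)
            ]
            truth = [fs.class_names[fs.y[i]] for i in test_idx]
            cm = confusion(truth, preds, positive_class)
        except Exception as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        fold_matrices.append(cm)
        fold_reports.append(metrics(cm))
    pooled_cm = fold_matrices[0]
    for cm in fold_matrices[1:]:
        pooled_cm = pooled_cm + cm
    return CVResult(
        fold_plan=plan,
        fold_matrices=fold_matrices,
        fold_reports=fold_reports,
        pooled_matrix=pooled_cm,
        pooled=metrics(pooled_cm),
        mean_of_folds=_mean_of_folds(fold_reports),
        positive_class=positive_class,
    )
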