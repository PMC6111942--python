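"""Delta associative memory: learning, dynamic threshold, classification.

The memory M is built in a single pass from a finite fundamental set of
known associations and stores every (pattern, label) pair grouped by
class.  Classification of an unknown query x^omega is difference-based:
for each stored pattern x^mu a difference score

    d_mu(x) = sum_j |x_j - x^mu_j|          (L1 aggregation, the default)

is computed, and a *dynamic threshold* theta(x) is recomputed fresh for
every query rather than fixed at training time.  Under the default
min-difference policy theta(x) is the smallest attained difference; the
candidate set is every stored pattern attaining it, and the predicted
label is the majority class among candidates, ties broken toward the
smallest class index.  Because a stored pattern is at zero difference
from itself, recall of a conflict-free fundamental set is perfect — the
classical correctness bar for an associative memory.

The difference operator is a pluggable strategy slot (``difference_fn``)
so an alternative component-wise operator can be substituted without
touching learning, evaluation or the CLI.

An optional rejection rule compares theta(x) against a magnitude-scaled
bound tau * mean_j |x_j| (the scaled-magnitude policy); queries whose
nearest stored pattern is farther than that bound are rejected rather
than forced into a class.  Rejection is off by default: benchmark
protocols force a binary decision for every test pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .dataio import ClassLabel, FundamentalSet, validate_schema
from .errors import DimensionMismatchError, FingerprintMismatchError, SchemaError

logger = logging.getLogger(__name__)

THRESHOLD_POLICIES = ("min-difference", "scaled-magnitude")

# Candidate-set membership: exact on all-integer data, else relative to n.
FLOAT_TOL_PER_DIM = 1e-9


def l1_difference(stored: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Sum of absolute component differences of x against every stored row."""
    return np.abs(stored - x).sum(axis=1)


@dataclass(frozen=True)
class MemoryConfig:
    """Classifier configuration.

    tau scales the rejection bound tau * mean|x_j|; it only matters when
    ``reject_enabled`` or when ``threshold_policy='scaled-magnitude'``.
    """

    threshold_policy: str = "min-difference"
    tau: float = 1.0
    reject_enabled: bool = False

    def __post_init__(self) -> None:
        if self.threshold_policy not in THRESHOLD_POLICIES:
            raise SchemaError(f"unknown threshold policy {self.threshold_policy!r}")
        if self.tau < 0:
            raise SchemaError("tau must be non-negative")


@dataclass(frozen=True)
class ClassificationResult:
    """Outcome of one query: label (None iff rejected), the dynamic
    threshold computed for this query, and how many stored patterns
    attained it."""

    label: ClassLabel | None
    threshold: float
    candidate_count: int

    @property
    def rejected(self) -> bool:
        return self.label is None


@dataclass
class DeltaMemory:
    """The learned structure M: every stored association plus config."""

    stored: np.ndarray
    labels: np.ndarray
    class_names: list[str]
    config: MemoryConfig = field(default_factory=MemoryConfig)
    source_fingerprint: tuple[int, int, str] | None = None
    difference_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] = l1_difference

    def __post_init__(self) -> None:
        self.stored = np.asarray(self.stored, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.stored.ndim != 2:
            raise SchemaError("stored patterns must form a 2-D array")
        if self.labels.shape != (self.stored.shape[0],):
            raise SchemaError("one label per stored pattern required")
        self._all_integer = bool(np.all(self.stored == np.round(self.stored)))

    @property
    def p(self) -> int:
        return self.stored.shape[0]

    @property
    def n(self) -> int:
        return self.stored.shape[1]

    def _as_query(self, x: Sequence[float] | np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        if x.shape[0] != self.n:
            raise DimensionMismatchError(
                f"query has dimensionality {x.shape[0]}, memory expects n={self.n}"
            )
        return x

    def _tolerance(self, x: np.ndarray) -> float:
        if self._all_integer and np.all(x == np.round(x)):
            return 0.0
        return FLOAT_TOL_PER_DIM * self.n


def learn(fs_transformed: FundamentalSet, config: MemoryConfig | None = None) -> DeltaMemory:
    """Single-pass, deterministic learning phase.

    Stores every association of the (already translated) fundamental set.
    Requires at least one pattern per class and at least two classes.
    Duplicate patterns carrying conflicting labels are stored but logged:
    recall of such a pattern cannot be correct for both labels.
    """
    problems = validate_schema(fs_transformed, for_learning=True, check_values=False)
    if problems:
        raise SchemaError("invalid fundamental set: " + "; ".join(problems))
    if fs_transformed.n_classes < 2:
        raise SchemaError("a classifier needs at least two classes")

    # conflicting duplicates: identical pattern rows under different labels
    order = np.lexsort(fs_transformed.X.T)
    Xs, ys = fs_transformed.X[order], fs_transformed.y[order]
    same = np.all(Xs[1:] == Xs[:-1], axis=1) & (ys[1:] != ys[:-1])
    if np.any(same):
        logger.warning(
            "%d duplicate pattern(s) stored under conflicting labels; "
            "recall of those patterns cannot be correct",
            int(same.sum()),
        )

    return DeltaMemory(
        stored=fs_transformed.X.copy(),
        labels=fs_transformed.y.copy(),
        class_names=list(fs_transformed.class_names),
        config=config or MemoryConfig(),
        source_fingerprint=fs_transformed.fingerprint(),
    )


def difference_scores(mem: DeltaMemory, x: Sequence[float] | np.ndarray) -> np.ndarray:
    """d_mu(x) for every stored mu, in storage order."""
    return mem.difference_fn(mem.stored, mem._as_query(x))


def dynamic_threshold(mem: DeltaMemory, x: Sequence[float] | np.ndarray) -> float:
    """The per-query threshold theta(x), recomputed fresh for each query.

    Under the default min-difference policy this is the minimum attained
    difference over all stored patterns; under scaled-magnitude it is
    tau * mean_j |x_j|.
    """
    xq = mem._as_query(x)
    if mem.config.threshold_policy == "scaled-magnitude":
        return float(mem.config.tau * np.abs(xq).mean())
    return float(difference_scores(mem, xq).min())


def _magnitude_bound(mem: DeltaMemory, x: np.ndarray) -> float:
    return float(mem.config.tau * np.abs(x).mean())


def classify(mem: DeltaMemory, x: Sequence[float] | np.ndarray) -> ClassificationResult:
    """Classify one query pattern.

    min-difference: candidates are the stored patterns attaining theta(x)
    exactly (tolerance 1e-9*n on non-integral data); the label is the
    majority class among candidates, ties to the smallest class index.
    scaled-magnitude: candidates are all stored patterns within the bound
    tau * mean|x_j|; an empty candidate set falls back to the nearest
    stored patterns (or is rejected when rejection is enabled).
    """
    xq = mem._as_query(x)
    d = difference_scores(mem, xq)
    tol = mem._tolerance(xq)
    d_min = float(d.min())

    if mem.config.threshold_policy == "scaled-magnitude":
        theta = _magnitude_bound(mem, xq)
        candidates = np.flatnonzero(d <= theta + tol)
        if candidates.size == 0:
            if mem.config.reject_enabled:
                return ClassificationResult(label=None, threshold=theta, candidate_count=0)
            candidates = np.flatnonzero(d <= d_min + tol)
    else:
        theta = d_min
        if mem.config.reject_enabled and theta > _magnitude_bound(mem, xq):
            return ClassificationResult(label=None, threshold=theta, candidate_count=0)
        candidates = np.flatnonzero(d <= theta + tol)

    votes = np.bincount(mem.labels[candidates], minlength=len(mem.class_names))
    winner = int(np.argmax(votes))  # argmax takes the smallest index on ties
    return ClassificationResult(
        label=ClassLabel(winner, mem.class_names[winner]),
        threshold=theta,
        candidate_count=int(candidates.size),
    )


def classify_many(mem: DeltaMemory, X: np.ndarray) -> list[ClassificationResult]:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return [classify(mem, row) for row in X]


def recall_fundamental(mem: DeltaMemory, fs: FundamentalSet) -> float:
    """Fraction of the memory's own fundamental set recalled correctly.

    ``fs`` must be the exact set the memory was learned from (checked by
    fingerprint).  Equals 1.0 whenever no two identical patterns carry
    different labels: each x^mu is at zero difference from itself.
    """
    if mem.source_fingerprint is not None and fs.fingerprint() != mem.source_fingerprint:
        raise FingerprintMismatchError(
            "fundamental set does not match the set this memory was learned from"
        )
    correct = 0
    for mu in range(fs.p):
        res = classify(mem, fs.X[mu])
        if res.label is not None and res.label.index == fs.y[mu]:
            correct += 1
    return correct / fs.p
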