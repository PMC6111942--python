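"""Brute-force reference classifier, independent of the package internals.

Pure-Python loops over all stored patterns and all candidates: no numpy
vectorisation, no shared code with deltamem.delta_am.  Used to confirm the
production classifier exactly, including tie cases.
"""

from __future__ import annotations


def oracle_classify(stored, labels, n_classes, x, tol=0.0):
    """Return (class_index, threshold, candidate_count) by exhaustive loops."""
    distances = []
    for row in stored:
        d = 0.0
        for a, b in zip(row, x):
            d += abs(a - b)
        distances.append(d)
    theta = min(distances)
    candidates = [i for i, d in enumerate(distances) if d <= theta + tol]
    votes = [0] * n_classes
    for i in candidates:
        votes[labels[i]] += 1
    best = max(votes)
    winner = min(c for c in range(n_classes) if votes[c] == best)
    return winner, theta, len(candidates)


def oracle_cv_predictions(X, y, n_classes, fold_assignments, k, offsets_mode="mean"):
    """Fold-by-fold predictions with per-fold mean/min translation, by loops."""
    preds = [None] * len(y)
    for fold in range(k):
        train = [i for i in range(len(y)) if fold_assignments[i] != fold]
        test = [i for i in range(len(y)) if fold_assignments[i] == fold]
        n = len(X[0])
        if offsets_mode == "mean":
            offsets = [sum(X[i][j] for i in train) / len(train) for j in range(n)]
        else:
            offsets = [min(X[i][j] for i in train) for j in range(n)]
        stored = [[X[i][j] - offsets[j] for j in range(n)] for i in train]
        stored_y = [y[i] for i in train]
        for i in test:
            q = [X[i][j] - offsets[j] for j in range(n)]
            winner, _, _ = oracle_classify(stored, stored_y, n_classes, q, tol=1e-9 * n)
            preds[i] = winner
    return preds
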