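"""Evaluation metrics reported by the experiment harness."""

from __future__ import annotations

import numpy as np

from .errors import DataError


def accuracy(truth, pred) -> float:
    """Percent of matching labels, 100 * matches / n."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise DataError(f"length mismatch: {truth.shape} vs {pred.shape}")
    if truth.size == 0:
        raise DataError("empty label vectors")
    return 100.0 * float(np.mean(truth == pred))


def confusion_counts(truth, pred, classes=None) -> dict:
    """Nested dict of counts[true_class][predicted_class]."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if classes is None:
        classes = np.unique(np.concatenate([truth, pred]))
    return {
        str(t): {str(p): int(np.sum((truth == t) & (pred == p))) for p in classes}
        for t in classes
    }


def per_class_recall(truth, pred) -> dict:
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    out = {}
    for c in np.unique(truth):
        mask = truth == c
        out[str(c)] = 100.0 * float(np.mean(pred[mask] == c))
    return out
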