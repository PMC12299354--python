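"""Evaluation metrics for binary dyskinesia classification.

Models are ranked by the unweighted (macro) F1 score — the arithmetic mean
of the per-class F1 scores — which weighs the rare dyskinetic class equally
with the majority class.  Accuracy and 2x2 confusion matrices are reported
alongside; Welch's unequal-variance t-test compares score sets between
models or representations.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sp_stats


def _check_binary(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.size == 0 or yp.size == 0:
        raise ValueError("empty label vectors")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return yt, yp


def confusion_matrix(y_true, y_pred) -> np.ndarray:
    """2x2 counts ``[[TN, FP], [FN, TP]]`` for binary labels."""
    yt, yp = _check_binary(y_true, y_pred)
    tn = int(np.sum((yt == 0) & (yp == 0)))
    fp = int(np.sum((yt == 0) & (yp == 1)))
    fn = int(np.sum((yt == 1) & (yp == 0)))
    tp = int(np.sum((yt == 1) & (yp == 1)))
    return np.array([[tn, fp], [fn, tp]])


def macro_f1(y_true, y_pred) -> float:
    """Unweighted macro F1: arithmetic mean of the per-class F1 scores.

    A class with zero predicted and zero true positives contributes F1 = 0.
    """
    yt, yp = _check_binary(y_true, y_pred)
    scores = []
    for cls in (0, 1):
        tp = np.sum((yt == cls) & (yp == cls))
        fp = np.sum((yt != cls) & (yp == cls))
        fn = np.sum((yt == cls) & (yp != cls))
        denom = 2 * tp + fp + fn
        scores.append(2 * tp / denom if denom > 0 else 0.0)
    return float(np.mean(scores))


def accuracy(y_true, y_pred) -> float:
    yt, yp = _check_binary(y_true, y_pred)
    return float(np.mean(yt == yp))


def welch_t_test(scores_a, scores_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, p)`` with Welch–Satterthwaite degrees of freedom.  Two
    zero-variance samples with equal means give ``(0.0, 1.0)``.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.inf) * np.sign(a.mean() - b.mean()), 0.0
    t, p = sp_stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
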