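"""Small shared scoring utilities."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["roc_auc", "brier_score", "roc_points"]


def roc_auc(y_true, scores) -> float:
    """ROC AUC via the Mann-Whitney identity (midranks handle ties)."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        return np.nan
    ranks = stats.rankdata(s)
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def brier_score(y_true, probs) -> float:
    """Mean squared error of predicted probabilities."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(probs, dtype=float)
    return float(np.mean((p - y) ** 2))


def roc_points(y_true, scores):
    """(fpr, tpr, thresholds) arrays for an ROC curve."""
    y = np.asarray(y_true, dtype=float)
    s = np.asarray(scores, dtype=float)
    order = np.argsort(-s, kind="mergesort")
    y = y[order]
    s = s[order]
    distinct = np.where(np.diff(s))[0]
    idx = np.r_[distinct, len(y) - 1]
    tps = np.cumsum(y)[idx]
    fps = (1 + idx) - tps
    n1 = y.sum()
    n0 = len(y) - n1
    tpr = np.r_[0.0, tps / max(n1, 1)]
    fpr = np.r_[0.0, fps / max(n0, 1)]
    thr = np.r_[np.inf, s[idx]]
    return fpr, tpr, thr
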