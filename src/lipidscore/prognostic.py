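"""Prognostic model comparison and two-step feature ranking.

``cv_evaluate`` scores declared feature sets with stratified k-fold logistic
models (pooled out-of-fold probabilities -> ROC/AUC, Brier, decile
calibration).  ``two_step_select`` runs repeated nested cross-validation:
L1-penalized logistic selection tuned on inner folds by accuracy, followed
by an RBF-kernel SVM on the selected features; selections from outer models
beating the accuracy gate are tallied into a frequency ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import brier_score, roc_auc, roc_points

__all__ = ["ModelReport", "FeatureRanking", "cv_evaluate", "two_step_select"]

log = logging.getLogger(__name__)


@dataclass
class ModelReport:
    name: str
    features: List[str]
    auc: float
    brier: float
    roc: pd.DataFrame                  # fpr, tpr, threshold
    calibration: pd.DataFrame          # bin, n, mean_pred, frac_pos
    oof_probs: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "features": self.features,
            "auc": self.auc,
            "brier": self.brier,
            "roc": self.roc.to_dict(orient="list"),
            "calibration": self.calibration.to_dict(orient="list"),
        }


@dataclass
class FeatureRanking:
    frequency: pd.Series               # per feature, descending
    top_k: List[str]
    n_accepted: int
    n_models: int
    acc_thresh: float

    def __post_init__(self) -> None:
        if ((self.frequency < 0) | (self.frequency > 1)).any():
            raise ValueError("selection frequencies must lie in [0, 1]")


def _calibration_table(y: np.ndarray, p: np.ndarray, bins: int = 10) -> pd.DataFrame:
    edges = np.quantile(p, np.linspace(0, 1, bins + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    idx = np.searchsorted(edges, p, side="right") - 1
    idx = np.clip(idx, 0, bins - 1)
    rows = []
    for b in range(bins):
        mask = idx == b
        if not mask.any():
            continue
        rows.append({"bin": b, "n": int(mask.sum()),
                     "mean_pred": float(p[mask].mean()),
                     "frac_pos": float(y[mask].mean())})
    return pd.DataFrame(rows)


def cv_evaluate(data: pd.DataFrame, feature_sets: Dict[str, Sequence[str]],
                outcome: str, k: int = 10, seed: int = 0) -> Dict[str, ModelReport]:
    """Stratified k-fold logistic evaluation of each feature set."""
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold

    y = data[outcome].to_numpy(dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("outcome must be binary")
    reports = {}
    for name, feats in feature_sets.items():
        feats = list(feats)
        missing = [f for f in feats if f not in data.columns]
        if missing:
            raise ValueError(f"features missing from data: {missing}")
        X = data[feats].to_numpy(dtype=float)
        n = len(y)
        k_eff = min(k, int(min((y == c).sum() for c in classes)))
        probs = np.empty(n)
        attempt = 0
        while True:
            skf = StratifiedKFold(n_splits=k_eff, shuffle=True,
                                  random_state=seed + attempt)
            ok = True
            for tr, te in skf.split(X, y):
                if len(np.unique(y[tr])) < 2:
                    ok = False
                    break
                clf = LogisticRegression(C=np.inf, max_iter=2000)
                clf.fit(X[tr], y[tr])
                probs[te] = clf.predict_proba(X[te])[:, 1]
            if ok:
                break
            attempt += 1
            log.warning("fold without both classes; refolding (attempt %d)",
                        attempt)
            if attempt > 10:
                raise RuntimeError("cannot produce valid stratified folds")
        fpr, tpr, thr = roc_points(y, probs)
        reports[name] = ModelReport(
            name=name, features=feats,
            auc=roc_auc(y, probs),
            brier=brier_score(y, probs),
            roc=pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}),
            calibration=_calibration_table(y, probs),
            oof_probs=probs,
        )
    return reports


def two_step_select(data: pd.DataFrame, features: Sequence[str], outcome: str,
                    repeats: int = 100, outer_k: int = 5, inner_k: int = 5,
                    acc_thresh: float = 0.8, top_k: int = 10,
                    seed: int = 0,
                    c_grid: Sequence[float] = (0.01, 0.1, 1.0, 10.0)
                    ) -> FeatureRanking:
    """Repeated nested CV: LASSO-logistic selection then RBF-SVM scoring.

    Features selected by outer-fold models whose held-out accuracy exceeds
    ``acc_thresh`` are tallied; the ranking is their selection frequency.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    features = list(features)
    if len(features) < top_k:
        raise ValueError(f"need >= top_k={top_k} candidate features")
    X_all = data[features].to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)

    counts = {f: 0 for f in features}
    n_accepted = 0
    n_models = 0
    rng = np.random.default_rng(seed)

    for rep in range(repeats):
        outer = StratifiedKFold(n_splits=outer_k, shuffle=True,
                                random_state=int(rng.integers(2**31 - 1)))
        for tr, te in outer.split(X_all, y):
            n_models += 1
            scaler = StandardScaler().fit(X_all[tr])
            Xtr = scaler.transform(X_all[tr])
            Xte = scaler.transform(X_all[te])
            ytr, yte = y[tr], y[te]

            # inner tuning of the L1 penalty by classification accuracy
            best_c, best_acc = c_grid[0], -np.inf
            inner = StratifiedKFold(n_splits=min(inner_k, int(min(
                (ytr == c).sum() for c in np.unique(ytr)))), shuffle=True,
                random_state=int(rng.integers(2**31 - 1)))
            for c in c_grid:
                lasso = LogisticRegression(l1_ratio=1.0, C=c,
                                           solver="liblinear", max_iter=2000)
                acc = cross_val_score(lasso, Xtr, ytr, cv=inner,
                                      scoring="accuracy").mean()
                if acc > best_acc:
                    best_acc, best_c = acc, c

            lasso = LogisticRegression(l1_ratio=1.0, C=best_c,
                                       solver="liblinear", max_iter=2000)
            lasso.fit(Xtr, ytr)
            selected = [features[j] for j in np.flatnonzero(lasso.coef_[0])]
            if not selected:
                continue
            cols = [features.index(f) for f in selected]
            svm = SVC(kernel="rbf")
            svm.fit(Xtr[:, cols], ytr)
            acc = float((svm.predict(Xte[:, cols]) == yte).mean())
            if acc > acc_thresh:
                n_accepted += 1
                for f in selected:
                    counts[f] += 1

    if n_accepted == 0:
        log.warning("no model passed the accuracy threshold %.2f", acc_thresh)
        freq = pd.Series(0.0, index=features)
    else:
        freq = pd.Series({f: counts[f] / n_accepted for f in features})
    freq = freq.sort_values(ascending=False, kind="mergesort")
    return FeatureRanking(freq, list(freq.index[:top_k]), n_accepted,
                          n_models, acc_thresh)
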