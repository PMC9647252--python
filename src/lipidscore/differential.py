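"""Outcome-associated lipid identification.

Two screening rules are provided: a covariate-adjusted per-species logistic
regression with BH-FDR correction, and a two-group Wilcoxon rank-sum screen.
Fold changes are log2 ratios of arithmetic group means of concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortTable, LipidomicsMatrix, ZMatrix

__all__ = ["DifferentialResult", "bh_adjust", "diff_logistic", "diff_wilcoxon"]

log = logging.getLogger(__name__)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-aware)."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


@dataclass
class DifferentialResult:
    """Per-species screen results plus the rule and thresholds used."""

    table: pd.DataFrame       # species, log2fc, p, p_adj, direction, passes, flagged
    rule: str = ""
    thresholds: dict = field(default_factory=dict)
    covariates: List[str] = field(default_factory=list)
    contrast: Tuple[str, str] = ("", "")

    @property
    def passing(self) -> List[str]:
        return list(self.table.loc[self.table["passes"], "species"])

    def up(self) -> List[str]:
        t = self.table
        return list(t.loc[t["passes"] & (t["log2fc"] > 0), "species"])

    def down(self) -> List[str]:
        t = self.table
        return list(t.loc[t["passes"] & (t["log2fc"] < 0), "species"])


# ---------------------------------------------------------------------------
# fast logistic regression (Newton/IRLS) for the per-species screen

def _logit_fit(X: np.ndarray, y: np.ndarray, max_iter: int = 40,
               tol: float = 1e-8) -> Tuple[np.ndarray, np.ndarray, bool, bool]:
    """Fit logistic regression; return (beta, se, converged, separated)."""
    n, k = X.shape
    beta = np.zeros(k)
    separated = False
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        eta = np.clip(eta, -30, 30)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        if np.max(np.abs(beta)) > 30:
            separated = True
            break
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        H.flat[:: k + 1] += 1e-10  # jitter for near-singular Hessians
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            separated = True
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)
        separated = True
    if not converged and np.max(np.abs(beta)) > 15:
        separated = True
    return beta, se, converged, separated


def _log2_fold_change(a: np.ndarray, b: np.ndarray) -> float:
    """log2 of the ratio of arithmetic means, group a over group b."""
    ma, mb = np.mean(a), np.mean(b)
    if ma <= 0 or mb <= 0:
        return np.nan
    return float(np.log2(ma / mb))


def diff_logistic(
    z: ZMatrix,
    cohort: Union[CohortTable, pd.DataFrame],
    contrast: Tuple[str, str] = ("non_resolving", "resolving"),
    timepoint: Optional[str] = "72h",
    covariates: Sequence[str] = ("age", "iss", "arm"),
    p_adj_thresh: float = 0.01,
    lfc_thresh: float = 0.4,
    outcome_col: str = "outcome",
    matrix: Optional[LipidomicsMatrix] = None,
) -> DifferentialResult:
    """Covariate-adjusted logistic screen: outcome ~ species_z + covariates.

    The species term's Wald p-value is BH-adjusted across species.  Fold
    changes are computed on concentrations (from ``matrix`` when given,
    otherwise from the inverse-transformed z-scores).  Species with perfect
    separation are flagged, given a NaN sentinel p, and never pass.
    """
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    df = df.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    if timepoint is not None:
        df = df[df["timepoint"].astype(str) == timepoint]
    df = df[df[outcome_col].isin(contrast)]
    df = df.loc[[i for i in df.index if i in z.z.index]]
    pos, neg = contrast
    n_pos = int((df[outcome_col] == pos).sum())
    n_neg = int((df[outcome_col] == neg).sum())
    if n_pos < 3 or n_neg < 3:
        raise ValueError(
            f"both contrast groups need >= 3 samples, got {n_pos}/{n_neg}")
    y = (df[outcome_col] == pos).to_numpy(dtype=float)

    cov_cols = []
    for c in covariates:
        if c not in df.columns:
            raise ValueError(f"covariate {c!r} missing from cohort table")
        col = df[c]
        if col.dtype == object:
            col = pd.Categorical(col).codes.astype(float)
        cov_cols.append(np.asarray(col, dtype=float))
    covX = np.column_stack(cov_cols) if cov_cols else np.empty((len(df), 0))
    # center/scale covariates for IRLS stability
    if covX.size:
        sd = covX.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        covX = (covX - covX.mean(axis=0)) / sd

    zsub = z.z.loc[df.index]
    conc = (matrix.values.loc[df.index] if matrix is not None
            else z.inverse().loc[df.index])
    mask_pos = y == 1

    records = []
    ones = np.ones((len(df), 1))
    for lab in z.z.columns:
        x = zsub[lab].to_numpy(dtype=float)
        X = np.hstack([ones, x[:, None], covX])
        beta, se, conv, sep = _logit_fit(X, y)
        if sep or not np.isfinite(se[1]) or se[1] == 0:
            pval = np.nan
            flagged = True
        else:
            zstat = beta[1] / se[1]
            pval = 2.0 * stats.norm.sf(abs(zstat))
            flagged = False
        cvals = conc[lab].to_numpy(dtype=float)
        lfc = _log2_fold_change(cvals[mask_pos], cvals[~mask_pos])
        records.append((lab, lfc, pval, flagged))

    tab = pd.DataFrame(records, columns=["species", "log2fc", "p", "flagged"])
    tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
    tab["direction"] = np.sign(tab["log2fc"]).fillna(0).astype(int)
    tab["passes"] = (~tab["flagged"]
                     & (tab["p_adj"] < p_adj_thresh)
                     & (tab["log2fc"].abs() > lfc_thresh))
    tab = tab.sort_values(["p_adj", "p"], kind="mergesort").reset_index(drop=True)
    tab = tab[["species", "log2fc", "p", "p_adj", "direction", "passes", "flagged"]]
    return DifferentialResult(
        tab, rule="logistic",
        thresholds={"p_adj": p_adj_thresh, "lfc": lfc_thresh},
        covariates=list(covariates), contrast=contrast)


def _ranksum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided rank-sum p: exact for n <= 10 per group without ties,
    normal approximation with tie correction otherwise."""
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= 10 and len(b) <= 10 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


def diff_wilcoxon(
    m: Union[LipidomicsMatrix, pd.DataFrame],
    groups: pd.Series,
    contrast: Optional[Tuple[str, str]] = None,
    p_thresh: float = 0.05,
    lfc_thresh: float = 0.4,
) -> DifferentialResult:
    """Two-group Wilcoxon rank-sum screen.

    ``groups`` maps sample id to group label.  A species passes when
    ``p < p_thresh`` and ``log2fc > lfc_thresh`` (one-directional: higher in
    the first contrast group).
    """
    values = m.values if isinstance(m, LipidomicsMatrix) else m
    groups = groups.loc[[i for i in groups.index if i in values.index]]
    labels = list(pd.unique(groups))
    if contrast is None:
        if len(labels) != 2:
            raise ValueError(f"need exactly two groups, got {labels}")
        contrast = (labels[0], labels[1])
    pos, neg = contrast
    ia = groups.index[groups == pos]
    ib = groups.index[groups == neg]
    if len(ia) < 3 or len(ib) < 3:
        raise ValueError(f"each group needs >= 3 samples, got {len(ia)}/{len(ib)}")

    records = []
    for lab in values.columns:
        a = values.loc[ia, lab].dropna().to_numpy(dtype=float)
        b = values.loc[ib, lab].dropna().to_numpy(dtype=float)
        if len(a) < 3 or len(b) < 3:
            records.append((lab, np.nan, np.nan, True))
            continue
        pval = _ranksum_p(a, b)
        lfc = _log2_fold_change(a, b)
        records.append((lab, lfc, pval, False))
    tab = pd.DataFrame(records, columns=["species", "log2fc", "p", "flagged"])
    tab["p_adj"] = bh_adjust(tab["p"].to_numpy())
    tab["direction"] = np.sign(tab["log2fc"]).fillna(0).astype(int)
    tab["passes"] = (~tab["flagged"] & (tab["p"] < p_thresh)
                     & (tab["log2fc"] > lfc_thresh))
    tab = tab.sort_values(["p", "p_adj"], kind="mergesort").reset_index(drop=True)
    tab = tab[["species", "log2fc", "p", "p_adj", "direction", "passes", "flagged"]]
    return DifferentialResult(
        tab, rule="wilcoxon",
        thresholds={"p": p_thresh, "lfc": lfc_thresh}, contrast=contrast)
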