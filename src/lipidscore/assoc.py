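"""Correlation analyses, the thresholded correlation network, and the
ICU-recovery (Kaplan-Meier) analysis.

Recovery conventions: the event is ICU discharge; early deaths (within the
death-day cutoff) are excluded; later deaths are carried at the maximum
observed ICU stay in the dataset and never recover; stays beyond the window
are censored at its end.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortTable, ValidationError, ZMatrix
from .nomenclature import parse_lipid_name

__all__ = [
    "correlation_matrix", "CorrelationNetwork", "correlation_network",
    "RecoveryCurve", "prepare_recovery", "recovery_km",
    "fit_logistic_gee", "fit_recovery_cox", "fit_outcome_models",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# correlation

def correlation_matrix(table: pd.DataFrame, method: str = "spearman"
                       ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise correlation with t-distribution p-values.

    ``p = 2 * P(T_{n-2} >= |r| * sqrt((n-2)/(1-r^2)))``.  Constant columns
    yield NaN coefficients and p-values.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    X = table.to_numpy(dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValueError("need at least 4 complete rows")
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.asarray(r, dtype=float)
    const = sd == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, np.where(const, np.nan, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        rr = np.clip(r, -1.0, 1.0)
        t = rr * np.sqrt((n - 2) / np.maximum(1.0 - rr * rr, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, np.nan)
    cols = table.columns
    return (pd.DataFrame(r, index=cols, columns=cols),
            pd.DataFrame(p, index=cols, columns=cols))


@dataclass
class CorrelationNetwork:
    """Thresholded Pearson network over selected species."""

    edges: pd.DataFrame                     # node1, node2, r
    nodes: List[str]
    threshold: float
    selection: Dict[str, int] = field(default_factory=dict)
    intra_class_edges: int = 0
    inter_class_edges: int = 0

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["node1"], row["node2"], r=float(row["r"]))
        return g


def _vst_top(values: pd.DataFrame, labels: Sequence[str], k: int) -> List[str]:
    """Top-k variable species by residual from a mean-variance trend.

    Log variance is regressed on log mean with lowess; species are ranked by
    the (standardized) residual, so high variance relative to abundance wins.
    """
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sub = values[list(labels)]
    mean = sub.mean(axis=0).to_numpy()
    var = sub.var(axis=0, ddof=1).to_numpy()
    ok = (mean > 0) & (var > 0)
    logm = np.log(np.maximum(mean, 1e-300))
    logv = np.log(np.maximum(var, 1e-300))
    if ok.sum() >= 5:
        trend = lowess(logv[ok], logm[ok], frac=0.7, return_sorted=False)
        resid = np.full(len(labels), -np.inf)
        resid[ok] = logv[ok] - trend
    else:
        resid = logv
    order = np.argsort(-resid, kind="mergesort")
    return [list(labels)[i] for i in order[:k]]


def correlation_network(
    z: ZMatrix,
    per_class_top: Optional[Dict[str, int]] = None,
    r_thresh: float = 0.7,
) -> CorrelationNetwork:
    """Build the thresholded Pearson network over per-class top-variable species.

    ``per_class_top`` maps class name to the number of most-variable species
    retained (vst-style selection on concentrations); classes not listed keep
    all species.  Edges connect pairs with ``|r| >= r_thresh`` (Pearson,
    computed on z-scores, which is identical to Pearson on concentrations).
    """
    if per_class_top is None:
        per_class_top = {"TAG": 100, "DAG": 30, "PE": 40, "PC": 40}
    by_class: Dict[str, List[str]] = {}
    for lab in z.z.columns:
        by_class.setdefault(parse_lipid_name(lab).lipid_class.value, []).append(lab)

    conc = z.inverse()
    kept: List[str] = []
    selection = {}
    for cls, labs in sorted(by_class.items()):
        k = per_class_top.get(cls)
        if k is None or k >= len(labs):
            chosen = list(labs)
        else:
            chosen = _vst_top(conc, labs, k)
        selection[cls] = len(chosen)
        kept.extend(chosen)

    sub = z.z[kept]
    r = np.corrcoef(sub.to_numpy(dtype=float), rowvar=False)
    cls_of = {lab: parse_lipid_name(lab).lipid_class.value for lab in kept}
    rows = []
    intra = inter = 0
    m = len(kept)
    for i in range(m):
        for j in range(i + 1, m):
            if abs(r[i, j]) >= r_thresh:
                rows.append((kept[i], kept[j], float(r[i, j])))
                if cls_of[kept[i]] == cls_of[kept[j]]:
                    intra += 1
                else:
                    inter += 1
    edges = pd.DataFrame(rows, columns=["node1", "node2", "r"])
    return CorrelationNetwork(edges, kept, r_thresh, selection, intra, inter)


# ---------------------------------------------------------------------------
# recovery analysis

@dataclass
class RecoveryCurve:
    """Product-limit curve of remaining-in-ICU probability."""

    group: str
    times: np.ndarray            # event/censor day grid
    probability: np.ndarray      # survival-in-ICU probability after each time
    at_risk: np.ndarray
    censored: np.ndarray         # number censored at each time
    n_subjects: int = 0


def prepare_recovery(cohort: Union[CohortTable, pd.DataFrame],
                     max_day: int = 30,
                     early_death_cut_days: int = 3,
                     late_death_max: Optional[float] = None) -> pd.DataFrame:
    """Return one row per subject with (time, event) under the conventions.

    * early deaths (death_day <= cutoff) are excluded;
    * later deaths carry ``late_death_max`` (default: maximum observed ICU
      stay in the dataset) and are treated as never recovering (censored);
    * times beyond ``max_day`` are censored at ``max_day``.
    """
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    df = df.copy()
    if "timepoint" in df.columns:
        df = df[df["timepoint"].astype(str) != "HC"]
    df = df.drop_duplicates(subset=["subject_id"])
    df = df[df["icu_los_days"].notna()]
    died = df.get("died", pd.Series(0, index=df.index)).fillna(0).astype(bool)
    early = died & (df["death_day"] <= early_death_cut_days)
    df = df[~early]
    died = df.get("died", pd.Series(0, index=df.index)).fillna(0).astype(bool)

    if late_death_max is None:
        late_death_max = float(df["icu_los_days"].max())
    time = df["icu_los_days"].astype(float).copy()
    event = (~died).astype(int)            # recovery = discharge alive
    time[died] = late_death_max
    event[died] = 0
    over = time > max_day
    time[over] = float(max_day)
    event[over] = 0
    out = pd.DataFrame({"subject_id": df["subject_id"], "time": time,
                        "event": event})
    if "outcome" in df.columns:
        out["outcome"] = df["outcome"].values
    return out.reset_index(drop=True)


def _km_curve(time: np.ndarray, event: np.ndarray, group: str) -> RecoveryCurve:
    order = np.argsort(time, kind="mergesort")
    time, event = time[order], event[order]
    grid = np.unique(time)
    n = len(time)
    probs, at_risk, censored = [], [], []
    s = 1.0
    for t in grid:
        r = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        c = int(np.sum((time == t) & (event == 0)))
        if r > 0:
            s *= 1.0 - d / r
        probs.append(s)
        at_risk.append(r)
        censored.append(c)
    return RecoveryCurve(group, grid, np.array(probs), np.array(at_risk),
                         np.array(censored), n_subjects=n)


def recovery_km(cohort: Union[CohortTable, pd.DataFrame],
                group_col: str = "outcome",
                max_day: int = 30,
                early_death_cut_days: int = 3
                ) -> Tuple[Dict[str, RecoveryCurve], pd.DataFrame]:
    """Kaplan-Meier recovery curves per group plus pairwise log-rank p-values."""
    from lifelines.statistics import logrank_test

    prepared = prepare_recovery(cohort, max_day=max_day,
                                early_death_cut_days=early_death_cut_days)
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    lookup = df.drop_duplicates("subject_id").set_index("subject_id")[group_col]
    prepared["group"] = prepared["subject_id"].map(lookup)

    curves = {}
    for grp, sub in prepared.groupby("group"):
        if len(sub) == 0:
            raise ValidationError(f"group {grp!r} has no subjects")
        curves[grp] = _km_curve(sub["time"].to_numpy(),
                                sub["event"].to_numpy(), str(grp))
    groups = sorted(curves)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1:]:
            sa = prepared[prepared["group"] == a]
            sb = prepared[prepared["group"] == b]
            res = logrank_test(sa["time"], sb["time"],
                               event_observed_A=sa["event"],
                               event_observed_B=sb["event"])
            rows.append((a, b, float(res.p_value)))
    pairwise = pd.DataFrame(rows, columns=["group_a", "group_b", "logrank_p"])
    return curves, pairwise


# ---------------------------------------------------------------------------
# outcome models

def fit_logistic_gee(df: pd.DataFrame, outcome: str,
                     covariates: Sequence[str],
                     cluster_col: Optional[str] = None) -> pd.DataFrame:
    """Clustered logistic fit (GEE, exchangeable) -> tidy effect table.

    Falls back to independent working correlation (= ordinary logistic) when
    no cluster column is given or there is a single cluster.
    """
    import statsmodels.api as sm

    work = df[[outcome, *covariates] + ([cluster_col] if cluster_col else [])]
    work = work.dropna()
    y = work[outcome].astype(float)
    X = sm.add_constant(work[list(covariates)].astype(float))
    if cluster_col and work[cluster_col].nunique() > 1:
        groups = work[cluster_col]
        cov_struct = sm.cov_struct.Exchangeable()
    else:
        groups = np.arange(len(work))
        cov_struct = sm.cov_struct.Independence()
    model = sm.GEE(y, X, groups=groups, family=sm.families.Binomial(),
                   cov_struct=cov_struct)
    try:
        res = model.fit(maxiter=200)
        converged = True
    except Exception as exc:
        log.warning("GEE fit failed: %s", exc)
        return pd.DataFrame({"term": covariates, "coef": np.nan, "or": np.nan,
                             "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                             "converged": False})
    ci = res.conf_int()
    rows = []
    for term in covariates:
        rows.append({
            "term": term,
            "coef": float(res.params[term]),
            "or": float(np.exp(res.params[term])),
            "ci_low": float(np.exp(ci.loc[term, 0])),
            "ci_high": float(np.exp(ci.loc[term, 1])),
            "p": float(res.pvalues[term]),
            "converged": converged,
        })
    return pd.DataFrame(rows)


def fit_recovery_cox(df: pd.DataFrame, covariates: Sequence[str],
                     duration_col: str = "time", event_col: str = "event",
                     cluster_col: Optional[str] = None,
                     return_lr_stat: bool = False):
    """Proportional-hazards fit for time-to-recovery -> tidy effect table.

    Cluster effects are handled with a robust (sandwich) variance grouped by
    ``cluster_col``.  Expects a table already prepared by
    :func:`prepare_recovery` (or supplying ``time``/``event`` directly).
    """
    from lifelines import CoxPHFitter

    cols = [duration_col, event_col, *covariates]
    if cluster_col:
        cols.append(cluster_col)
    work = df[cols].dropna().copy()
    fitter = CoxPHFitter()
    kwargs = {}
    if cluster_col and work[cluster_col].nunique() > 1:
        kwargs = {"cluster_col": cluster_col, "robust": True}
    elif cluster_col:
        work = work.drop(columns=[cluster_col])
    fitter.fit(work, duration_col=duration_col, event_col=event_col, **kwargs)
    summ = fitter.summary
    rows = []
    for term in covariates:
        rows.append({
            "term": term,
            "coef": float(summ.loc[term, "coef"]),
            "se": float(summ.loc[term, "se(coef)"]),
            "hr": float(summ.loc[term, "exp(coef)"]),
            "ci_low": float(np.exp(summ.loc[term, "coef lower 95%"])),
            "ci_high": float(np.exp(summ.loc[term, "coef upper 95%"])),
            "p": float(summ.loc[term, "p"]),
            "converged": True,
        })
    out = pd.DataFrame(rows)
    if return_lr_stat:
        lr = float(fitter.log_likelihood_ratio_test().test_statistic)
        return out, lr
    return out


def fit_outcome_models(cohort: Union[CohortTable, pd.DataFrame],
                       model_specs: Sequence[dict]) -> pd.DataFrame:
    """Fit a list of declared outcome models and stack their effect tables.

    Each spec is a dict:
    ``{"name", "kind": "logistic"|"cox", "outcome"/"duration"+"event",
    "covariates", "cluster" (optional)}``.
    """
    df = cohort.table if isinstance(cohort, CohortTable) else cohort
    out = []
    for spec in model_specs:
        try:
            if spec["kind"] == "logistic":
                eff = fit_logistic_gee(df, spec["outcome"], spec["covariates"],
                                       cluster_col=spec.get("cluster"))
            elif spec["kind"] == "cox":
                eff = fit_recovery_cox(df, spec["covariates"],
                                       duration_col=spec.get("duration", "time"),
                                       event_col=spec.get("event", "event"),
                                       cluster_col=spec.get("cluster"))
            else:
                raise ValueError(f"unknown model kind {spec['kind']!r}")
        except Exception as exc:
            log.warning("model %s failed: %s", spec.get("name"), exc)
            eff = pd.DataFrame({"term": spec["covariates"], "coef": np.nan,
                                "p": np.nan, "converged": False})
        eff.insert(0, "model", spec.get("name", spec["kind"]))
        out.append(eff)
    return pd.concat(out, ignore_index=True)
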