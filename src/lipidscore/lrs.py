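"""Construction and application of the lipid reprogramming score (LRS).

The score is the mean z-score of a small PE panel.  Construction proceeds in
three stages: (1) intersect species across datasets to find a cross-platform
candidate pool, (2) screen the pool for sign-consistent correlation with the
differentially abundant lipids, (3) pick the candidate set with the strongest
cross-dataset outcome association (hazard ratio for recovery in trauma
cohorts, odds ratio for severity cohorts) and freeze its reference
statistics and tertile cutpoints into a reusable model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .data import CohortTable, LipidomicsMatrix, ZMatrix
from .differential import DifferentialResult
from .nomenclature import LipidName, parse_lipid_name

__all__ = [
    "LRSModel", "common_lipids", "screen_candidates",
    "sensitivity_select", "compute_lrs", "lrs_categories",
]

log = logging.getLogger(__name__)


@dataclass
class LRSModel:
    """A frozen scoring model: panel, reference stats, tertile cutpoints."""

    panel: List[str]
    mean: Dict[str, float]
    sd: Dict[str, float]
    cutpoints: Optional[Tuple[float, float]] = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.panel:
            raise ValueError("panel must be non-empty")
        if self.cutpoints is not None:
            lo, hi = self.cutpoints
            if lo > hi:
                raise ValueError("cutpoints must be ordered")

    def to_json(self, path) -> None:
        payload = {
            "panel": self.panel,
            "mean": self.mean,
            "sd": self.sd,
            "cutpoints": list(self.cutpoints) if self.cutpoints else None,
            "provenance": self.provenance,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=str)

    @classmethod
    def from_json(cls, path) -> "LRSModel":
        with open(path) as fh:
            payload = json.load(fh)
        cut = payload.get("cutpoints")
        return cls(payload["panel"], payload["mean"], payload["sd"],
                   tuple(cut) if cut else None, payload.get("provenance", {}))


def common_lipids(datasets: Sequence[Union[LipidomicsMatrix, ZMatrix]]
                  ) -> List[LipidName]:
    """Species present in every dataset (canonical class + sorted chains).

    Summed-TAG entries are matched at the class + total carbons:double-bonds
    level against expanded TAG species.
    """
    if len(datasets) < 2:
        raise ValueError("need at least 2 datasets")

    def keysets(ds):
        species = ds.species
        exact = {s.key for s in species}
        tag_totals = {s.total_key for s in species
                      if s.lipid_class.value == "TAG"}
        return exact, tag_totals

    first = datasets[0].species
    sets = [keysets(d) for d in datasets]
    out = []
    for s in first:
        exact_everywhere = all(s.key in ex for ex, _ in sets)
        tag_everywhere = (s.lipid_class.value == "TAG"
                          and all(s.total_key in tt for _, tt in sets))
        if exact_everywhere or tag_everywhere:
            out.append(s)
    return out


def screen_candidates(
    pool: Sequence[Union[str, LipidName]],
    diff: DifferentialResult,
    z: ZMatrix,
    samples: Optional[Sequence[str]] = None,
    min_abs_r: float = 0.0,
) -> Tuple[List[str], pd.DataFrame]:
    """Sign-consistency screen of candidate species against differential lipids.

    A pool member is retained iff it correlates positively (r > min_abs_r)
    with every up-regulated lipid and negatively (r < -min_abs_r) with every
    down-regulated lipid.  Returns (retained labels, correlation matrix).
    """
    pool_labels = [p.format() if isinstance(p, LipidName) else
                   parse_lipid_name(p).format() for p in pool]
    missing = [p for p in pool_labels if p not in z.z.columns]
    if missing:
        raise ValueError(f"pool species absent from z matrix: {missing}")
    up = [s for s in diff.up() if s in z.z.columns]
    down = [s for s in diff.down() if s in z.z.columns]
    targets = up + down
    zdf = z.z if samples is None else z.z.loc[list(samples)]

    corr = pd.DataFrame(index=pool_labels, columns=targets, dtype=float)
    for pl in pool_labels:
        x = zdf[pl]
        for t in targets:
            corr.loc[pl, t] = x.corr(zdf[t])

    retained = []
    for pl in pool_labels:
        ok_up = all(corr.loc[pl, t] > min_abs_r for t in up if t != pl)
        ok_down = all(corr.loc[pl, t] < -min_abs_r for t in down if t != pl)
        if ok_up and ok_down:
            retained.append(pl)
    return retained, corr


def compute_lrs(model: LRSModel,
                z_or_matrix: Union[ZMatrix, LipidomicsMatrix, pd.DataFrame],
                min_present: Optional[int] = None) -> pd.Series:
    """Per-sample LRS: arithmetic mean of the panel z-scores.

    Raw concentrations are z-scored with the model's stored reference stats.
    ``min_present`` allows scoring when at least that many panel species are
    available; by default all must be present.
    """
    if isinstance(z_or_matrix, ZMatrix):
        zdf = z_or_matrix.z
    elif isinstance(z_or_matrix, LipidomicsMatrix):
        values = z_or_matrix.values
        mean = pd.Series(model.mean)
        sd = pd.Series(model.sd)
        present = [c for c in model.panel if c in values.columns]
        zdf = (values[present] - mean[present]) / sd[present]
    else:
        zdf = z_or_matrix
    present = [c for c in model.panel if c in zdf.columns]
    absent = [c for c in model.panel if c not in zdf.columns]
    needed = len(model.panel) if min_present is None else min_present
    if len(present) < needed:
        raise ValueError(f"panel species absent: {absent}")
    scores = zdf[present].mean(axis=1)
    scores.name = "lrs"
    return scores


def lrs_categories(scores: pd.Series,
                   cutpoints: Optional[Tuple[float, float]] = None,
                   population: Optional[Sequence[str]] = None
                   ) -> Tuple[pd.Series, Tuple[float, float]]:
    """Assign Low/Medium/High by tertiles of a declared reference population.

    Cutpoints use the type-7 (linear interpolation) quantile convention.
    ``Low: s <= q1/3``, ``Medium: q1/3 < s <= q2/3``, ``High: s > q2/3``.
    """
    if cutpoints is None:
        ref = scores if population is None else scores.loc[list(population)]
        if len(ref) < 3 or ref.nunique() < 3:
            raise ValueError("need >= 3 distinct reference scores for tertiles")
        lo = float(np.quantile(ref.to_numpy(), 1.0 / 3.0, method="linear"))
        hi = float(np.quantile(ref.to_numpy(), 2.0 / 3.0, method="linear"))
        cutpoints = (lo, hi)
    lo, hi = cutpoints
    cats = pd.Series("Medium", index=scores.index, dtype=object)
    cats[scores <= lo] = "Low"
    cats[scores > hi] = "High"
    cats.name = "lrs_category"
    return cats, cutpoints


def _score_effect_trauma(score: pd.Series, cohort: pd.DataFrame,
                         cluster_col: Optional[str] = "site_id",
                         score_timepoint: str = "72h") -> Optional[float]:
    """(log HR, se, LR statistic) of recovery per 1 sd of score.

    The score is taken at ``score_timepoint`` for each subject and joined
    against the per-subject recovery table (late-death/censoring conventions
    applied by :func:`lipidscore.assoc.prepare_recovery`).
    """
    from .assoc import prepare_recovery, fit_recovery_cox

    df = cohort.copy()
    rec = prepare_recovery(df)
    rows = df[df["timepoint"].astype(str) == score_timepoint]
    if "sample_id" in rows.columns:
        rows = rows.set_index("sample_id")
    rows = rows.loc[[i for i in rows.index if i in score.index]]
    if rows.empty:
        return None
    subj_score = pd.Series(score.loc[rows.index].to_numpy(),
                           index=rows["subject_id"].to_numpy())
    work = rec.set_index("subject_id")
    work = work.loc[[s for s in work.index if s in subj_score.index]].copy()
    work["score"] = subj_score.loc[work.index].to_numpy()
    if cluster_col and cluster_col in df.columns:
        cl = df.drop_duplicates("subject_id").set_index("subject_id")[cluster_col]
        work[cluster_col] = cl.loc[work.index].to_numpy()
    else:
        cluster_col = None
    sd = work["score"].std(ddof=1)
    if not np.isfinite(sd) or sd == 0 or len(work) < 10:
        return None
    work["score"] = (work["score"] - work["score"].mean()) / sd
    try:
        eff, lr = fit_recovery_cox(work, covariates=["score"],
                                   cluster_col=cluster_col,
                                   return_lr_stat=True)
        row = eff.loc[eff["term"] == "score"].iloc[0]
        return float(row["coef"]), float(row["se"]), float(lr)
    except Exception as exc:  # non-convergence -> unavailable
        log.warning("trauma score effect failed: %s", exc)
        return None


def _score_effect_severity(score: pd.Series, cohort: pd.DataFrame,
                           severity_col: str = "severity",
                           positive: str = "severe") -> Optional[float]:
    """(log OR, se, LR statistic) of severity per 1 sd of score."""
    from .differential import _logit_fit
    df = cohort.copy()
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    df = df[df[severity_col].isin([positive, "non_severe"])]
    df = df.loc[[i for i in df.index if i in score.index]]
    y = (df[severity_col] == positive).to_numpy(dtype=float)
    if y.sum() < 3 or (1 - y).sum() < 3:
        return None
    s = score.loc[df.index].to_numpy(dtype=float)
    sd = s.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return None
    x = (s - s.mean()) / sd
    X = np.column_stack([np.ones_like(x), x])
    beta, se, conv, sep = _logit_fit(X, y)
    if sep or not np.isfinite(se[1]) or se[1] <= 0:
        return None
    # deviance-based LR vs the intercept-only model (robust near separation)
    pbar = y.mean()
    dev0 = -2.0 * (y.sum() * np.log(pbar)
                   + (len(y) - y.sum()) * np.log(1 - pbar))
    eta = np.clip(X @ beta, -30, 30)
    mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-12, 1 - 1e-12)
    dev1 = -2.0 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    return float(beta[1]), float(se[1]), float(max(dev0 - dev1, 0.0))


def sensitivity_select(
    candidate_sets: Dict[str, Sequence[str]],
    datasets: Sequence[dict],
    tertile_population: Optional[Sequence[str]] = None,
) -> Tuple[LRSModel, pd.DataFrame]:
    """Pick the candidate panel with the strongest cross-dataset association.

    Each dataset descriptor is a dict with keys ``id``, ``kind``
    ("trauma" or "severity"), ``z`` (ZMatrix) and ``cohort`` (DataFrame or
    CohortTable).  Within each dataset candidate sets are ranked by the
    likelihood-ratio statistic of the score term (only effects with the
    hypothesized sign count: recovery HR < 1 for trauma, severity OR > 1);
    ranks are averaged across datasets and the best average wins, ties
    broken toward the smaller panel.  Raw |log effect| and Wald rankings are
    both unstable under quasi-separation (the Hauck-Donner effect deflates
    Wald statistics exactly for the strongest panels), so association
    strength is measured on the likelihood scale.

    Returns the fitted :class:`LRSModel` (reference stats from the first
    trauma dataset) and the full sensitivity table.
    """
    if not candidate_sets:
        raise ValueError("no candidate sets supplied")
    rows = []
    effects: Dict[str, Dict[str, Optional[float]]] = {}
    for set_id, panel in candidate_sets.items():
        panel = [parse_lipid_name(p).format() if isinstance(p, str) else p.format()
                 for p in panel]
        effects[set_id] = {}
        for ds in datasets:
            z = ds["z"]
            cohort = ds["cohort"]
            cdf = cohort.table if isinstance(cohort, CohortTable) else cohort
            if not all(p in z.z.columns for p in panel):
                effects[set_id][ds["id"]] = None
                rows.append({"set_id": set_id, "dataset": ds["id"],
                             "effect": np.nan, "log_effect": np.nan,
                             "available": False})
                continue
            score = z.z[panel].mean(axis=1)
            if ds["kind"] == "trauma":
                eff = _score_effect_trauma(score, cdf,
                                           cluster_col=ds.get("cluster", "site_id"))
            else:
                eff = _score_effect_severity(score, cdf)
            effects[set_id][ds["id"]] = eff
            coef = eff[0] if eff is not None else np.nan
            se = eff[1] if eff is not None else np.nan
            lr = eff[2] if eff is not None else np.nan
            rows.append({
                "set_id": set_id, "dataset": ds["id"],
                "effect": np.exp(coef), "log_effect": coef, "se": se,
                "ci_low": np.exp(coef - 1.96 * se),
                "ci_high": np.exp(coef + 1.96 * se),
                "lr_stat": lr,
                "available": eff is not None,
            })
    table = pd.DataFrame(rows)

    # composite rule: per-dataset rank of the sign-consistent LR statistic,
    # average across datasets; unavailable/wrong-sign cells get the worst rank
    set_ids = list(candidate_sets)
    n_sets = len(set_ids)

    def _strength(eff, kind):
        if eff is None:
            return -np.inf
        coef, _se, lr = eff
        good_sign = (kind == "trauma" and coef < 0) or \
                    (kind != "trauma" and coef > 0)
        if not good_sign or not np.isfinite(lr):
            return -np.inf
        return lr

    avg_ranks = {}
    for set_id in set_ids:
        ranks = []
        for ds in datasets:
            scores = [_strength(effects[other].get(ds["id"]), ds["kind"])
                      for other in set_ids]
            order = sorted(range(n_sets), key=lambda i: -scores[i])
            rank = order.index(set_ids.index(set_id)) + 1
            if scores[set_ids.index(set_id)] == -np.inf:
                rank = n_sets + 1  # penalized
            ranks.append(rank)
        avg_ranks[set_id] = float(np.mean(ranks))

    winner = min(set_ids,
                 key=lambda s: (avg_ranks[s], len(candidate_sets[s]), s))
    panel = [parse_lipid_name(p).format() if isinstance(p, str) else p.format()
             for p in candidate_sets[winner]]

    ref_ds = next((d for d in datasets if d["kind"] == "trauma"), datasets[0])
    zref: ZMatrix = ref_ds["z"]
    model = LRSModel(
        panel=panel,
        mean={p: float(zref.mean[p]) for p in panel},
        sd={p: float(zref.sd[p]) for p in panel},
        provenance={
            "selected_set": winner,
            "avg_ranks": avg_ranks,
            "candidate_sets": {k: list(map(str, v))
                               for k, v in candidate_sets.items()},
        },
    )
    scores = compute_lrs(model, zref)
    if tertile_population is not None:
        _, cut = lrs_categories(scores, population=tertile_population)
        model.cutpoints = cut
    return model, table
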