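"""End-to-end score-construction pipeline.

Chains preprocessing, the covariate-adjusted differential screen, the
cross-dataset candidate pool, the sign-consistency screen, and the
sensitivity selection into a single call that returns a frozen scoring
model.  Used by the CLI and by the synthetic-recovery checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import CohortTable, LipidomicsMatrix, ZMatrix
from .differential import DifferentialResult, diff_logistic
from .lrs import (LRSModel, common_lipids, compute_lrs, lrs_categories,
                  screen_candidates, sensitivity_select)
from .nomenclature import parse_lipid_name
from .preprocess import filter_missing, impute_min, zscore

__all__ = ["PipelineResult", "preprocess_matrix", "build_lrs"]

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    model: LRSModel
    diff: DifferentialResult
    pool: List[str]
    screened: List[str]
    sensitivity_table: pd.DataFrame
    scores: pd.Series
    categories: Optional[pd.Series] = None


def preprocess_matrix(m: LipidomicsMatrix, max_missing: float = 0.20
                      ) -> Tuple[LipidomicsMatrix, ZMatrix]:
    """filter -> impute -> z-score; returns (imputed matrix, z matrix)."""
    filtered = filter_missing(m, max_missing)
    imputed = impute_min(filtered)
    return imputed, zscore(imputed)


def _elevated_in_dataset(processed: dict, raw: dict,
                         p_thresh: float = 0.05,
                         lfc_thresh: float = 0.4) -> List[str]:
    """Species elevated in the adverse group of an auxiliary dataset
    (two-group rank-sum screen on the imputed concentrations)."""
    from .differential import diff_wilcoxon
    from .preprocess import filter_missing, impute_min

    cdf = raw["cohort"]
    cdf = cdf.table if isinstance(cdf, CohortTable) else cdf
    imputed = impute_min(filter_missing(raw["matrix"]))
    if raw["kind"] == "severity":
        sel = cdf[cdf["severity"].isin(["severe", "non_severe"])]
        groups = pd.Series(sel["severity"].to_numpy(),
                           index=sel["sample_id"].to_numpy())
        contrast = ("severe", "non_severe")
    else:
        sel = cdf[(cdf["timepoint"].astype(str) == "72h")
                  & cdf["outcome"].isin(["non_resolving", "resolving"])]
        groups = pd.Series(sel["outcome"].to_numpy(),
                           index=sel["sample_id"].to_numpy())
        contrast = ("non_resolving", "resolving")
    res = diff_wilcoxon(imputed, groups, contrast=contrast,
                        p_thresh=p_thresh, lfc_thresh=lfc_thresh)
    return res.up()


def build_lrs(
    trauma_matrix: LipidomicsMatrix,
    trauma_cohort: CohortTable,
    aux_datasets: Sequence[dict],
    contrast: Tuple[str, str] = ("non_resolving", "resolving"),
    timepoint: str = "72h",
    covariates: Sequence[str] = ("age", "iss", "arm"),
    max_missing: float = 0.20,
    candidate_class: str = "PE",
) -> PipelineResult:
    """Construct an LRS model from a trauma training cohort plus auxiliary
    datasets (each ``{"id", "kind": "trauma"|"severity", "matrix", "cohort"}``).

    Candidate pool: ``candidate_class`` species common to every dataset.
    Screen: sign-consistent correlation with the differential lipids over the
    contrast samples at the analysis timepoint.  Candidate sets compared in
    the sensitivity stage: full pool, screened subset, and the single
    strongest screened species.
    """
    _, z_train = preprocess_matrix(trauma_matrix, max_missing)
    cdf = (trauma_cohort.table if isinstance(trauma_cohort, CohortTable)
           else trauma_cohort)

    diff = diff_logistic(z_train, cdf, contrast=contrast, timepoint=timepoint,
                         covariates=covariates)

    processed_aux = []
    for ds in aux_datasets:
        _, z_aux = preprocess_matrix(ds["matrix"], max_missing)
        processed_aux.append({"id": ds["id"], "kind": ds["kind"], "z": z_aux,
                              "cohort": ds["cohort"]})

    matrices = [z_train] + [d["z"] for d in processed_aux]
    shared = common_lipids(matrices)
    pool = [s.format() for s in shared
            if s.lipid_class.value == candidate_class]
    if not pool:
        raise ValueError(f"no common {candidate_class} species across datasets")

    contrast_samples = cdf[
        (cdf["timepoint"].astype(str) == timepoint)
        & cdf["outcome"].isin(contrast)]
    sample_ids = [s for s in contrast_samples["sample_id"]
                  if s in z_train.z.index]
    screened, corr = screen_candidates(pool, diff, z_train,
                                       samples=sample_ids)
    if not screened:
        log.warning("screen retained no candidates; falling back to pool")
        screened = list(pool)

    # cross-dataset consistency: keep screened species elevated in at least
    # two auxiliary datasets (rank-sum screen within each); with a single
    # auxiliary dataset that one must agree
    elevated_counts = {s: 0 for s in screened}
    for ds, proc in zip(aux_datasets, processed_aux):
        elevated = set(_elevated_in_dataset(proc, ds))
        for s in screened:
            elevated_counts[s] += s in elevated
    need = min(2, len(aux_datasets))
    consistent = [s for s in screened if elevated_counts[s] >= need]

    up = [t for t in diff.up() if t in corr.columns]
    strength = corr.loc[screened, up].mean(axis=1) if up else \
        pd.Series(0.0, index=screened)
    top_source = consistent if consistent else screened
    top1 = [strength.loc[top_source].idxmax()]

    # candidate structure: full pool / cross-dataset-consistent subset /
    # single strongest species
    candidate_sets: Dict[str, List[str]] = {"pool": list(pool)}
    if consistent and set(consistent) != set(pool):
        candidate_sets["consistent"] = list(consistent)
    candidate_sets["top1"] = top1

    datasets = [{"id": "train", "kind": "trauma", "z": z_train,
                 "cohort": cdf}] + processed_aux

    alive_72h = cdf[(cdf["timepoint"].astype(str) == timepoint)
                    & (cdf["outcome"] != "healthy")]
    tertile_pop = [s for s in alive_72h["sample_id"] if s in z_train.z.index]

    model, table = sensitivity_select(candidate_sets, datasets,
                                      tertile_population=tertile_pop or None)
    scores = compute_lrs(model, z_train)
    cats = None
    if model.cutpoints is not None:
        cats, _ = lrs_categories(scores, cutpoints=model.cutpoints)
    model.provenance.update({
        "pool": pool,
        "screened": screened,
        "n_differential": len(diff.passing),
        "contrast": list(contrast),
        "timepoint": timepoint,
    })
    return PipelineResult(model, diff, pool, screened, table, scores, cats)
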