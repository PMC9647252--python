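"""Severity-stratified (COVID-like) cohort generator.

Single baseline sample per subject; the planted PE panel is selectively
elevated in severe subjects and shares a latent factor; CRP and lymphocyte
count are coupled to severity.
"""

from __future__ import annotations

import math
from typing import Tuple

import numpy as np
import pandas as pd

from ..data import CohortTable, LipidomicsMatrix
from ._panel import build_panel
from .config import CovidGenConfig, PlantedTruth

__all__ = ["generate_covid_cohort"]


def generate_covid_cohort(
    cfg: CovidGenConfig, seed: int
) -> Tuple[LipidomicsMatrix, CohortTable, PlantedTruth]:
    cfg.validate()
    rng = np.random.default_rng(seed)

    fixed = list(cfg.planted_pe) + list(cfg.decoy_pe)
    panel = build_panel(cfg.species_counts, fixed, rng)
    p = len(panel)
    col_idx = {lab: j for j, lab in enumerate(panel)}
    up_idx = np.array([col_idx[s] for s in cfg.planted_pe], dtype=int)
    decoy_idx = np.array([col_idx[s] for s in cfg.decoy_pe], dtype=int)

    from ..nomenclature import parse_lipid_name
    log_mu = np.array([
        cfg.class_log_loc.get(parse_lipid_name(lab).lipid_class.value, 0.0)
        + rng.normal(0.0, cfg.species_log_spread)
        for lab in panel
    ])

    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv ** 2))
    groups = (["healthy"] * cfg.n_healthy + ["non_severe"] * cfg.n_non_severe
              + ["severe"] * cfg.n_severe)

    rows, values, sample_ids = [], [], []
    for i, grp in enumerate(groups, start=1):
        subj = f"C{i:03d}"
        mult = np.ones(p)
        if grp == "severe":
            mult[up_idx] *= cfg.pe_effect
            mult[decoy_idx] *= cfg.decoy_effect
        g = rng.normal()
        eps = rng.normal(size=p)
        noise = eps.copy()
        noise[up_idx] = math.sqrt(cfg.rho) * g + math.sqrt(1 - cfg.rho) * eps[up_idx]
        logx = log_mu + np.log(mult) + sigma * noise
        values.append(np.exp(logx))
        sample_ids.append(f"{subj}_baseline")

        sev_shift = {"healthy": -0.5, "non_severe": 0.0, "severe": 1.0}[grp]
        rows.append({
            "sample_id": sample_ids[-1],
            "subject_id": subj,
            "timepoint": "baseline",
            "severity": grp,
            "age": float(np.clip(rng.normal(55, 15), 20, 95)),
            "sex": int(rng.random() < 0.5),
            "crp": float(np.exp(rng.normal(3.0, 0.5) + cfg.crp_coef * sev_shift)),
            "lymphocyte": float(np.exp(rng.normal(0.3, 0.3)
                                       + cfg.lymph_coef * sev_shift)),
        })

    mat = np.asarray(values, dtype=float)
    miss = rng.random(mat.shape) < cfg.missing_rate
    miss[0, miss.all(axis=0)] = False
    mat[miss] = np.nan

    vdf = pd.DataFrame(mat, index=sample_ids, columns=panel)
    matrix = LipidomicsMatrix(vdf, dataset_id=f"synthetic-covid-{seed}")
    cohort = CohortTable(pd.DataFrame(rows))
    truth = PlantedTruth(
        planted_pe=list(cfg.planted_pe),
        elevated_species=list(cfg.planted_pe),
        decoy_pe=list(cfg.decoy_pe),
        effect_sizes={"pe_effect": cfg.pe_effect},
    )
    return matrix, cohort, truth
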