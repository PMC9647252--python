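"""Longitudinal trauma-cohort generator.

Concentrations are log-normal with multiplicative group/time effects applied
on the log scale.  Patients carry samples at 0/24/72 h except early
non-survivors, who contribute the 0 h sample only.  A designated lipid block
(5 PE plus configurable TAG/DAG/CER, and a small suppressed set) is raised or
lowered selectively in non-resolvers at 72 h and shares a latent factor so
the block is internally correlated.
"""

from __future__ import annotations

import math
from typing import Dict, List, Tuple

import numpy as np
import pandas as pd

from ..data import CohortTable, LipidomicsMatrix
from ..nomenclature import parse_lipid_name
from ._panel import build_panel
from .config import PlantedTruth, TraumaGenConfig

__all__ = ["generate_trauma_cohort"]

_TIMEPOINTS = ["0h", "24h", "72h"]

MEDIATOR_PANELS = {
    "subset1": ["IL6", "IL8", "MCP1"],
    "subset2": ["IL4", "IL5", "IL7"],
    "subset3": ["IL9", "IL22", "IL33"],
}
OTHER_BIOMARKERS = ["sVEGFR", "syndecan1", "adiponectin"]


def _log_sigma(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def generate_trauma_cohort(
    cfg: TraumaGenConfig, seed: int
) -> Tuple[LipidomicsMatrix, CohortTable, PlantedTruth]:
    """Generate (matrix, cohort, truth) for a synthetic trauma study."""
    cfg.validate()
    rng = np.random.default_rng(seed)

    # ---- species panel and planted block -------------------------------
    fixed = list(cfg.planted_pe) + list(cfg.decoy_pe)
    panel = build_panel(cfg.species_counts, fixed, rng)
    by_class: Dict[str, List[str]] = {}
    for lab in panel:
        by_class.setdefault(parse_lipid_name(lab).lipid_class.value, []).append(lab)

    elevated = list(cfg.planted_pe)
    protected = set(fixed)
    for cls, k in cfg.planted_other_counts.items():
        candidates = [s for s in by_class.get(cls, []) if s not in protected]
        pick = list(rng.choice(candidates, size=min(k, len(candidates)),
                               replace=False))
        elevated.extend(pick)
        protected.update(pick)
    down_pool = [s for s in by_class.get("LPC", []) if s not in protected]
    suppressed = list(rng.choice(down_pool,
                                 size=min(cfg.planted_down_count, len(down_pool)),
                                 replace=False))
    protected.update(suppressed)

    p = len(panel)
    col_idx = {lab: j for j, lab in enumerate(panel)}
    up_idx = np.array([col_idx[s] for s in elevated], dtype=int)
    down_idx = np.array([col_idx[s] for s in suppressed], dtype=int)
    # decoy PE: mild opposite mean shift at 72 h, noise independent of the block
    decoy_idx = np.array([col_idx[s] for s in cfg.decoy_pe], dtype=int)

    # per-species baseline log-concentration
    log_mu = np.empty(p)
    for lab in panel:
        cls = parse_lipid_name(lab).lipid_class.value
        loc = cfg.class_log_loc.get(cls, 0.0)
        log_mu[col_idx[lab]] = loc + rng.normal(0.0, cfg.species_log_spread)

    # ---- subjects -------------------------------------------------------
    subjects = []
    sid = 0
    for _ in range(cfg.n_healthy):
        sid += 1
        subjects.append({"subject_id": f"H{sid:03d}", "group": "healthy",
                         "arm": "none"})
    for (outcome, arm), n in sorted(cfg.n_per_cell.items()):
        for _ in range(n):
            sid += 1
            subjects.append({"subject_id": f"P{sid:03d}", "group": outcome,
                             "arm": arm})

    rows = []
    for s in subjects:
        grp, arm = s["group"], s["arm"]
        rec = dict(s)
        rec["site_id"] = int(rng.integers(1, cfg.n_sites + 1))
        rec["age"] = float(np.clip(rng.normal(46, 16), 18, 90))
        rec["sex"] = int(rng.random() < 0.75)
        rec["bmi"] = float(np.clip(rng.normal(27, 5), 16, 50))
        if grp == "healthy":
            rec.update(died=0, death_day=np.nan, icu_los_days=np.nan,
                       iss=np.nan, tbi=np.nan, triss=np.nan, inr=np.nan)
        else:
            if grp == "resolving":
                iss_mu, triss_ab, inr_mu = 21, (8, 2), 0.20
            elif grp == "non_resolving":
                iss_mu, triss_ab, inr_mu = 30, (5, 3), 0.30
            else:
                iss_mu, triss_ab, inr_mu = 24, (2, 5), 0.45
            rec["iss"] = int(np.clip(rng.normal(iss_mu, 8), 4, 75))
            rec["tbi"] = int(rng.random() < (0.35 if grp == "resolving" else 0.6))
            rec["triss"] = float(np.clip(rng.beta(*triss_ab), 0.01, 0.99))
            rec["inr"] = float(np.exp(rng.normal(inr_mu, 0.15)))
            if grp == "resolving":
                rec.update(died=0, death_day=np.nan,
                           icu_los_days=int(rng.integers(1, 7)))
            elif grp == "non_resolving":
                if rng.random() < cfg.late_death_frac:
                    dd = int(rng.integers(4, 26))
                    rec.update(died=1, death_day=dd, icu_los_days=dd)
                else:
                    rec.update(died=0, death_day=np.nan,
                               icu_los_days=int(rng.integers(7, 36)))
            else:  # early non-survivor
                rec.update(died=1, death_day=int(rng.integers(1, 4)),
                           icu_los_days=int(rng.integers(1, 4)))
        rows.append(rec)
    subj_df = pd.DataFrame(rows)

    # ---- samples --------------------------------------------------------
    sigma = _log_sigma(cfg.noise_cv)
    att = cfg.tp_attenuation
    sample_rows = []
    values = []
    sample_ids = []

    def _multipliers(grp: str, arm: str, tp: str) -> np.ndarray:
        mult = np.ones(p)
        if grp == "healthy":
            return mult
        if tp == "0h":
            base = cfg.drop0h[grp]
            logm = math.log(base)
            if arm == "TP":
                logm *= (1.0 - att)
            mult[:] = math.exp(logm)
        elif tp == "24h":
            mult[:] = cfg.drop24h[grp]
        else:
            mult[:] = cfg.drop72h[grp]
            if grp == "non_resolving":
                mult[up_idx] *= cfg.rise72h
                mult[down_idx] *= cfg.fall72h
                mult[decoy_idx] *= cfg.decoy_fall72h
        return mult

    for rec in subj_df.to_dict("records"):
        grp = rec["group"]
        u = rng.normal(0.0, cfg.subject_sd)
        if grp == "healthy":
            tps = ["HC"]
        elif grp == "early_nonsurvivor":
            tps = ["0h"]
        else:
            tps = list(_TIMEPOINTS)
        for tp in tps:
            mult = _multipliers(grp, rec["arm"], tp if tp != "HC" else "0h") \
                if grp != "healthy" else np.ones(p)
            g = rng.normal()  # latent factor shared by the planted block
            eps = rng.normal(size=p)
            noise = eps.copy()
            r = math.sqrt(cfg.rho)
            q = math.sqrt(1.0 - cfg.rho)
            noise[up_idx] = r * g + q * eps[up_idx]
            noise[down_idx] = -r * g + q * eps[down_idx]
            logx = log_mu + u + np.log(mult) + sigma * noise
            values.append(np.exp(logx))
            sample_ids.append(f"{rec['subject_id']}_{tp}")
            srow = {k: rec[k] for k in rec}
            srow["timepoint"] = tp
            srow["sample_id"] = sample_ids[-1]
            # biomarkers: coupled to non-resolution, drawn per sample
            shift = {"resolving": 0.0, "non_resolving": 1.0,
                     "early_nonsurvivor": 0.5, "healthy": -0.5}[grp]
            for subset, markers in MEDIATOR_PANELS.items():
                coef = cfg.mediator_coef[subset]
                for mk in markers:
                    srow[mk] = float(np.exp(rng.normal(2.0, 0.6) + coef * shift))
            srow["sVEGFR"] = float(np.exp(rng.normal(5.0, 0.4) + 0.6 * shift))
            srow["syndecan1"] = float(np.exp(rng.normal(4.0, 0.4) + 0.6 * shift))
            srow["adiponectin"] = float(np.exp(rng.normal(2.5, 0.4) - 0.5 * shift))
            sample_rows.append(srow)

    mat = np.asarray(values)

    # ---- missingness ----------------------------------------------------
    n_samples = mat.shape[0]
    eligible = np.array([lab not in protected for lab in panel])
    n_bad = int(round(cfg.high_missing_frac * p))
    bad_idx = rng.choice(np.flatnonzero(eligible), size=n_bad, replace=False) \
        if n_bad else np.array([], dtype=int)
    miss = rng.random(mat.shape) < cfg.missing_rate
    if len(bad_idx):
        miss[:, bad_idx] |= rng.random((n_samples, len(bad_idx))) < cfg.high_missing_rate
    # keep at least one observed value per species
    all_missing = miss.all(axis=0)
    miss[0, all_missing] = False
    mat = mat.astype(float)
    mat[miss] = np.nan

    vdf = pd.DataFrame(mat, index=sample_ids, columns=panel)
    matrix = LipidomicsMatrix(vdf, dataset_id=f"synthetic-trauma-{seed}")

    cohort_df = pd.DataFrame(sample_rows)
    cohort_df = cohort_df.rename(columns={"group": "outcome"})
    ordered = ["sample_id", "subject_id", "timepoint", "outcome", "arm",
               "died", "death_day", "icu_los_days", "age", "sex", "iss",
               "tbi", "triss", "inr", "site_id", "bmi"]
    others = [c for c in cohort_df.columns if c not in ordered]
    cohort = CohortTable(cohort_df[ordered + others])

    truth = PlantedTruth(
        planted_pe=list(cfg.planted_pe),
        elevated_species=elevated,
        suppressed_species=suppressed,
        decoy_pe=list(cfg.decoy_pe),
        mediator_signs={k: (1 if v > 0 else -1)
                        for k, v in cfg.mediator_coef.items()},
        effect_sizes={"rise72h": cfg.rise72h, "fall72h": cfg.fall72h,
                      "tp_attenuation": cfg.tp_attenuation},
    )
    return matrix, cohort, truth
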