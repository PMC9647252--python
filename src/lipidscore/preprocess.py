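"""Preprocessing of lipidomics matrices.

Pipeline order: drop species with excessive missingness, impute remaining
missing cells with the per-species observed minimum, then z-score against a
declared reference sample set.  Re-running the chain on its own output is a
no-op.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data import ClassSummary, LipidomicsMatrix, ValidationError, ZMatrix
from .nomenclature import LipidName

__all__ = ["filter_missing", "impute_min", "class_summaries", "zscore"]

log = logging.getLogger(__name__)


def filter_missing(m: LipidomicsMatrix, max_frac: float = 0.20) -> LipidomicsMatrix:
    """Drop species whose missing fraction is strictly greater than ``max_frac``.

    A species missing in exactly ``max_frac`` of samples is retained (the rule
    discards only fractions *over* the cutoff).  Removal is logged and recorded
    in the returned matrix's provenance.
    """
    if not (0 <= max_frac < 1):
        raise ValueError(f"max_frac must be in [0, 1), got {max_frac}")
    if m.values.shape[0] == 0 or m.values.shape[1] == 0:
        raise ValidationError("cannot filter an empty matrix")
    frac = m.missing_fraction()
    removed = list(frac.index[frac > max_frac])
    kept = [c for c in m.values.columns if c not in set(removed)]
    log.info("filter_missing: removed %d/%d species (max_frac=%.3g)",
             len(removed), m.values.shape[1], max_frac)
    species = [s for s in m.species if s.format() in set(kept)]
    prov = dict(m.provenance)
    prov["filter_missing"] = {"max_frac": max_frac, "removed": removed}
    return LipidomicsMatrix(m.values[kept], species, m.dataset_id, m.units, prov)


def impute_min(m: LipidomicsMatrix) -> LipidomicsMatrix:
    """Replace each missing cell with the per-species minimum observed value."""
    fully_missing = list(m.values.columns[m.values.isna().all(axis=0)])
    if fully_missing:
        raise ValidationError(
            f"species with no observed values (filter first): {fully_missing}"
        )
    mins = m.values.min(axis=0, skipna=True)
    values = m.values.fillna(mins)
    prov = dict(m.provenance)
    prov["impute_min"] = {"n_imputed": int(m.values.isna().to_numpy().sum())}
    return LipidomicsMatrix(values, list(m.species), m.dataset_id, m.units, prov)


def class_summaries(m: LipidomicsMatrix) -> ClassSummary:
    """Class totals, fatty-acid composition, and SFA/USFA decomposition.

    Each chain of a species contributes the species concentration divided by
    the number of chains (equal-chain weighting), so the per-class chain-mass
    decomposition is exhaustive: SFA + USFA equals the class total.
    Summed-dialect species (no chain list) count toward class totals only.
    """
    if m.values.isna().any().any():
        raise ValidationError("class_summaries requires an imputed matrix")
    samples = m.values.index
    classes = sorted({s.lipid_class.value for s in m.species})
    totals = pd.DataFrame(0.0, index=samples, columns=classes)
    sfa = pd.DataFrame(0.0, index=samples, columns=classes)
    usfa = pd.DataFrame(0.0, index=samples, columns=classes)
    fa_parts: dict = {cls: {} for cls in classes}

    for sp in m.species:
        col = m.values[sp.format()]
        cls = sp.lipid_class.value
        totals[cls] += col
        if sp.chains is None:
            continue
        w = 1.0 / len(sp.chains)
        for c, d in sp.chains:
            key = f"{c}:{d}"
            fa_parts[cls].setdefault(key, pd.Series(0.0, index=samples))
            fa_parts[cls][key] = fa_parts[cls][key] + col * w
            if d == 0:
                sfa[cls] += col * w
            else:
                usfa[cls] += col * w

    fa_composition = {}
    for cls in classes:
        if not fa_parts[cls]:
            continue
        part = pd.DataFrame(fa_parts[cls])
        denom = part.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            comp = part.div(denom, axis=0)
        fa_composition[cls] = comp
    return ClassSummary(totals, fa_composition, sfa, usfa)


def zscore(m: LipidomicsMatrix, reference: Optional[Sequence[str]] = None,
           ddof: int = 1) -> ZMatrix:
    """Z-score each species against a reference sample subset (default: all).

    Uses the sample (ddof=1) standard deviation.  The reference mean/sd are
    stored so held-out samples and external datasets can be scored later.
    """
    if m.values.isna().any().any():
        raise ValidationError("zscore requires an imputed matrix")
    if reference is None:
        ref = m.values
        ref_name = "all"
    else:
        ref = m.values.loc[list(reference)]
        ref_name = f"subset(n={len(ref)})"
    if len(ref) < 2:
        raise ValidationError("reference must contain at least 2 samples")
    mean = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=ddof)
    zero = list(sd.index[sd <= 0])
    if zero:
        raise ValidationError(f"zero-variance species in reference: {zero}")
    z = (m.values - mean) / sd
    return ZMatrix(z, mean, sd, reference_set=ref_name, ddof=ddof,
                   species=list(m.species))
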