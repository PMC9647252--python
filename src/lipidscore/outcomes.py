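"""Outcome labelling for trauma cohorts.

Three-way patient classification from survival, death day, and ICU length of
stay; healthy controls are labelled separately.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import CohortTable, ValidationError

__all__ = ["assign_outcome", "OUTCOMES"]

OUTCOMES = ["healthy", "resolving", "non_resolving", "early_nonsurvivor"]


def assign_outcome(cohort: CohortTable, icu_cut_days: int = 7,
                   early_death_cut_days: int = 3) -> CohortTable:
    """Derive the outcome label for every row of a trauma cohort table.

    Rules (per subject):

    * non-survivor with ``death_day <= early_death_cut_days`` -> early_nonsurvivor
    * non-survivor with ``death_day > early_death_cut_days`` -> non_resolving
    * survivor with ``icu_los_days >= icu_cut_days`` -> non_resolving
    * survivor with ``icu_los_days < icu_cut_days`` -> resolving
    * healthy controls (timepoint ``HC`` or ``arm == 'none'``) -> healthy
    """
    df = cohort.table.copy()
    healthy = df["timepoint"].astype(str).eq("HC")
    if "arm" in df.columns:
        healthy |= df["arm"].astype(str).eq("none")

    died = df.get("died", pd.Series(0, index=df.index)).fillna(0).astype(bool)
    if (died & ~healthy & df["death_day"].isna()).any():
        bad = df.loc[died & df["death_day"].isna(), "subject_id"].tolist()
        raise ValidationError(f"died without death_day: {bad}")

    outcome = pd.Series("resolving", index=df.index, dtype=object)
    early = died & (df["death_day"] <= early_death_cut_days)
    late_death = died & (df["death_day"] > early_death_cut_days)
    long_icu = ~died & (df["icu_los_days"] >= icu_cut_days)
    outcome[long_icu | late_death] = "non_resolving"
    outcome[early] = "early_nonsurvivor"
    outcome[healthy] = "healthy"
    df["outcome"] = outcome

    # a subject must receive one label only
    per_subj = df.groupby("subject_id")["outcome"].nunique()
    if (per_subj > 1).any():
        bad = list(per_subj.index[per_subj > 1])
        raise ValidationError(f"inconsistent outcome within subject: {bad}")
    return CohortTable(df)
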