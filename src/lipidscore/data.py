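"""Data containers and file I/O for lipidomics matrices and cohort tables.

Matrices are stored wide: rows are samples, columns are canonical lipid
labels.  Missing values are encoded as NaN internally and as empty cells or
``NA`` on disk.  Cohort tables are per-sample clinical annotation with one
row per subject-timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .nomenclature import LipidName, parse_lipid_name

__all__ = [
    "LipidomicsMatrix",
    "ZMatrix",
    "ClassSummary",
    "CohortTable",
    "read_matrix",
    "read_cohort",
]

#: Columns a cohort table must provide for trauma-style cohorts.
COHORT_REQUIRED_COLUMNS = ["subject_id", "timepoint"]

#: Optional, validated when present.
COHORT_KNOWN_COLUMNS = [
    "subject_id", "timepoint", "died", "death_day", "icu_los_days",
    "outcome", "arm", "age", "sex", "iss", "tbi", "triss", "inr",
    "site_id", "bmi", "severity",
]


class ValidationError(ValueError):
    """Raised when a container violates its structural invariants."""


@dataclass
class LipidomicsMatrix:
    """Samples x species concentration matrix with missingness mask.

    ``values`` has sample ids as index and canonical lipid labels as columns;
    NaN marks a missing measurement.
    """

    values: pd.DataFrame
    species: List[LipidName] = field(default_factory=list)
    dataset_id: str = ""
    units: str = "uM"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [parse_lipid_name(c) for c in self.values.columns]
        # normalize columns to canonical labels
        self.values = self.values.copy()
        self.values.columns = [s.format() for s in self.species]
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        cols = pd.Index(self.values.columns)
        if cols.duplicated().any():
            dups = cols[cols.duplicated()].tolist()
            raise ValidationError(f"duplicate species labels: {dups}")
        arr = self.values.to_numpy(dtype=float)
        finite_or_nan = np.isnan(arr) | np.isfinite(arr)
        if not finite_or_nan.all():
            raise ValidationError("matrix contains non-finite values")
        observed = arr[~np.isnan(arr)]
        if observed.size and observed.min() < 0:
            raise ValidationError("concentrations must be non-negative")

    @property
    def sample_ids(self) -> List[str]:
        return list(self.values.index)

    @property
    def labels(self) -> List[str]:
        return list(self.values.columns)

    def missing_fraction(self) -> pd.Series:
        """Per-species fraction of missing cells."""
        return self.values.isna().mean(axis=0)

    def subset_species(self, labels: Sequence[str]) -> "LipidomicsMatrix":
        keep = [lab for lab in self.values.columns if lab in set(labels)]
        species = [s for s in self.species if s.format() in set(keep)]
        return LipidomicsMatrix(
            self.values[keep], species, self.dataset_id, self.units,
            dict(self.provenance),
        )

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class ZMatrix:
    """Z-scored matrix plus the per-species reference statistics.

    The stored mean/sd (sample sd, ddof=1) allow scoring of new samples and
    exact inversion back to concentrations.
    """

    z: pd.DataFrame
    mean: pd.Series
    sd: pd.Series
    reference_set: str = "all"
    ddof: int = 1
    species: List[LipidName] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.species:
            self.species = [parse_lipid_name(c) for c in self.z.columns]
        if (self.sd <= 0).any():
            bad = list(self.sd.index[self.sd <= 0])
            raise ValidationError(f"non-positive sd for species: {bad}")

    @property
    def labels(self) -> List[str]:
        return list(self.z.columns)

    def score(self, values: pd.DataFrame) -> pd.DataFrame:
        """Z-score new concentration rows using the stored reference stats."""
        cols = [c for c in self.z.columns if c in values.columns]
        return (values[cols] - self.mean[cols]) / self.sd[cols]

    def inverse(self) -> pd.DataFrame:
        """Recover the original concentrations."""
        return self.z * self.sd + self.mean

    def to_tsv(self, path) -> None:
        out = self.z.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")


@dataclass
class ClassSummary:
    """Per-sample class totals and fatty-acid composition.

    ``fa_composition`` maps class name to a samples x "c:d" proportion table;
    ``sfa`` / ``usfa`` decompose each class total into contributions from
    saturated (d == 0) and unsaturated (d > 0) chains.
    """

    class_totals: pd.DataFrame
    fa_composition: dict
    sfa: pd.DataFrame
    usfa: pd.DataFrame

    @property
    def total(self) -> pd.Series:
        """Total lipid concentration per sample."""
        return self.class_totals.sum(axis=1)


@dataclass
class CohortTable:
    """Per-sample clinical annotation table.

    One row per subject-timepoint.  Booleans are stored as 0/1.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.table
        for col in COHORT_REQUIRED_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"cohort table missing column {col!r}")
        if df.duplicated(subset=["subject_id", "timepoint"]).any():
            raise ValidationError("duplicate subject-timepoint rows")
        if "died" in df.columns and "death_day" in df.columns:
            died = df["died"].fillna(0).astype(bool)
            has_day = df["death_day"].notna()
            if (died & ~has_day).any():
                raise ValidationError("died=1 rows must carry death_day")
            if (~died & has_day).any():
                raise ValidationError("death_day present for survivors")
        if "icu_los_days" in df.columns:
            los = df["icu_los_days"].dropna()
            if (los < 0).any():
                raise ValidationError("icu_los_days must be >= 0")
        if "triss" in df.columns:
            tr = df["triss"].dropna()
            if ((tr < 0) | (tr > 1)).any():
                raise ValidationError("triss must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def _read_table(path, sep: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, na_values=["NA", ""], keep_default_na=True)


def read_matrix(path, dataset_id: str = "", units: str = "uM",
                sep: Optional[str] = None) -> LipidomicsMatrix:
    """Read a wide lipidomics matrix (first column = sample id)."""
    df = _read_table(path, sep)
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    return LipidomicsMatrix(df.astype(float), dataset_id=dataset_id or str(path),
                            units=units)


def read_cohort(path, sep: Optional[str] = None) -> CohortTable:
    df = _read_table(path, sep)
    df["subject_id"] = df["subject_id"].astype(str)
    return CohortTable(df)
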