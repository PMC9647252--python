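"""Configuration objects for the synthetic generators.

Effect sizes here are artifact choices calibrated so that the downstream
pipeline reproduces the qualitative temporal patterns (global early drop,
persistent suppression in resolvers, correlated selective late rise of a
planted lipid block); they are configuration, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

__all__ = ["TraumaGenConfig", "CovidGenConfig", "SEMConfig", "PlantedTruth",
           "ConfigError", "PLANTED_PE", "DECOY_PE"]


class ConfigError(ValueError):
    """Raised with the list of invalid config fields."""


#: Default planted PE panel (5 species) and decoy PE shared across cohorts.
PLANTED_PE = [
    "PE(16:0_18:2)",
    "PE(16:0_20:4)",
    "PE(16:0_22:6)",
    "PE(18:0_18:1)",
    "PE(18:0_22:6)",
]
DECOY_PE = ["PE(16:0_16:0)", "PE(18:1_18:1)", "PE(18:0_20:3)"]


def _default_species_counts() -> Dict[str, int]:
    # 14 classes, 996 species total; the four largest classes dominate
    return {
        "TAG": 518, "PE": 128, "PC": 121, "DAG": 58,
        "SM": 40, "CER": 25, "LPC": 25, "PI": 22, "LPE": 15,
        "MAG": 10, "HCER": 10, "CE": 10, "LCER": 8, "DCER": 6,
    }


def _default_class_log_loc() -> Dict[str, float]:
    return {
        "TAG": 1.0, "PE": -0.5, "PC": 1.5, "DAG": 0.0, "SM": 1.0,
        "CER": -1.0, "LPC": 0.5, "PI": 0.0, "LPE": -1.0, "MAG": -1.5,
        "HCER": -1.5, "CE": 2.0, "LCER": -2.0, "DCER": -2.5,
    }


@dataclass
class TraumaGenConfig:
    """Generator settings for the longitudinal trauma cohort."""

    # cohort sizes: patients per (outcome, arm) cell and healthy controls
    n_per_cell: Dict[Tuple[str, str], int] = field(default_factory=lambda: {
        ("resolving", "standard_care"): 20, ("resolving", "TP"): 20,
        ("non_resolving", "standard_care"): 20, ("non_resolving", "TP"): 20,
        ("early_nonsurvivor", "standard_care"): 20, ("early_nonsurvivor", "TP"): 20,
    })
    n_healthy: int = 17

    # species panel
    species_counts: Dict[str, int] = field(default_factory=_default_species_counts)
    class_log_loc: Dict[str, float] = field(default_factory=_default_class_log_loc)
    species_log_spread: float = 0.8

    # group/time multipliers applied on the log scale (relative to healthy)
    drop0h: Dict[str, float] = field(default_factory=lambda: {
        "resolving": 0.6, "non_resolving": 0.6, "early_nonsurvivor": 0.3})
    drop24h: Dict[str, float] = field(default_factory=lambda: {
        "resolving": 0.55, "non_resolving": 0.6})
    drop72h: Dict[str, float] = field(default_factory=lambda: {
        "resolving": 0.6, "non_resolving": 0.6})

    # planted block: selective rise (and a small suppressed set) at 72 h in
    # non-resolvers, correlated within the block
    planted_pe: List[str] = field(default_factory=lambda: list(PLANTED_PE))
    decoy_pe: List[str] = field(default_factory=lambda: list(DECOY_PE))
    planted_other_counts: Dict[str, int] = field(default_factory=lambda: {
        "TAG": 10, "DAG": 5, "CER": 3})
    planted_down_count: int = 3          # suppressed LPC-like species
    rise72h: float = 1.8
    fall72h: float = 0.5
    decoy_fall72h: float = 0.8           # mild suppression of the decoy PE
    rho: float = 0.5                     # within-block correlation

    # treatment effect: fraction of the 0 h log-drop removed under TP
    tp_attenuation: float = 0.5

    # measurement model
    noise_cv: float = 0.25
    subject_sd: float = 0.15
    missing_rate: float = 0.02
    high_missing_frac: float = 0.03      # fraction of species made low quality
    high_missing_rate: float = 0.5

    # mediator couplings (log-scale shift for non-resolving vs resolving)
    mediator_coef: Dict[str, float] = field(default_factory=lambda: {
        "subset1": 1.0, "subset2": -0.8, "subset3": -0.8})
    n_sites: int = 6
    late_death_frac: float = 0.3         # of non-resolvers

    def validate(self) -> None:
        errors = []
        for name, d in [("drop0h", self.drop0h), ("drop24h", self.drop24h),
                        ("drop72h", self.drop72h)]:
            for k, v in d.items():
                if v <= 0:
                    errors.append(f"{name}[{k}] must be > 0, got {v}")
        if self.rise72h <= 0:
            errors.append(f"rise72h must be > 0, got {self.rise72h}")
        if self.fall72h <= 0:
            errors.append(f"fall72h must be > 0, got {self.fall72h}")
        if not (0 <= self.rho < 1):
            errors.append(f"rho must be in [0, 1), got {self.rho}")
        if not (0 <= self.tp_attenuation <= 1):
            errors.append(f"tp_attenuation must be in [0, 1], got {self.tp_attenuation}")
        for cell, n in self.n_per_cell.items():
            if n < 1:
                errors.append(f"n_per_cell[{cell}] must be >= 1, got {n}")
        if self.n_healthy < 1:
            errors.append("n_healthy must be >= 1")
        for cls, n in self.species_counts.items():
            if n < 1:
                errors.append(f"species_counts[{cls}] must be >= 1, got {n}")
        if self.noise_cv <= 0:
            errors.append("noise_cv must be > 0")
        if not (0 <= self.missing_rate < 1):
            errors.append("missing_rate must be in [0, 1)")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class CovidGenConfig:
    """Generator settings for the severity (COVID-like) cohort."""

    n_healthy: int = 25
    n_non_severe: int = 25
    n_severe: int = 20

    species_counts: Dict[str, int] = field(default_factory=lambda: {
        "PE": 8, "PC": 10, "PI": 4, "SM": 6})
    class_log_loc: Dict[str, float] = field(default_factory=_default_class_log_loc)
    species_log_spread: float = 0.6

    planted_pe: List[str] = field(default_factory=lambda: list(PLANTED_PE))
    decoy_pe: List[str] = field(default_factory=lambda: list(DECOY_PE))
    pe_effect: float = 1.6               # planted PE multiplier in severe
    decoy_effect: float = 0.8            # mild decoy suppression in severe
    rho: float = 0.5
    noise_cv: float = 0.3
    missing_rate: float = 0.01

    crp_coef: float = 1.0                # log-scale shift in severe
    lymph_coef: float = -0.5

    def validate(self) -> None:
        errors = []
        if self.pe_effect <= 0:
            errors.append(f"pe_effect must be > 0, got {self.pe_effect}")
        if not (0 <= self.rho < 1):
            errors.append(f"rho must be in [0, 1), got {self.rho}")
        for name in ("n_healthy", "n_non_severe", "n_severe"):
            if getattr(self, name) < 1:
                errors.append(f"{name} must be >= 1")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class SEMConfig:
    """Linear/logistic structural equation model over a known DAG."""

    variables: List[Tuple[str, str]]          # (name, "continuous"|"binary")
    edges: List[Tuple[str, str, float]]       # (parent, child, weight)
    noise_sd: Dict[str, float] = field(default_factory=dict)
    intercepts: Dict[str, float] = field(default_factory=dict)
    n: int = 1000

    def validate(self) -> None:
        errors = []
        names = [v for v, _ in self.variables]
        if len(set(names)) != len(names):
            errors.append("duplicate variable names")
        types = dict(self.variables)
        for t in types.values():
            if t not in ("continuous", "binary"):
                errors.append(f"unknown variable type {t!r}")
        for u, v, _ in self.edges:
            if u not in types or v not in types:
                errors.append(f"edge ({u}, {v}) references unknown variable")
        if self.n < 1:
            errors.append("n must be >= 1")
        if errors:
            raise ConfigError("; ".join(errors))


@dataclass
class PlantedTruth:
    """Ground truth planted by a generator, for downstream recovery checks."""

    planted_pe: List[str] = field(default_factory=list)
    elevated_species: List[str] = field(default_factory=list)
    suppressed_species: List[str] = field(default_factory=list)
    decoy_pe: List[str] = field(default_factory=list)
    mediator_signs: Dict[str, int] = field(default_factory=dict)
    effect_sizes: Dict[str, float] = field(default_factory=dict)
    dag_edges: List[Tuple[str, str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "planted_pe": self.planted_pe,
            "elevated_species": self.elevated_species,
            "suppressed_species": self.suppressed_species,
            "decoy_pe": self.decoy_pe,
            "mediator_signs": self.mediator_signs,
            "effect_sizes": self.effect_sizes,
            "dag_edges": [list(e) for e in self.dag_edges],
        }
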