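"""Reference multi-dataset synthetic suite.

One trauma training cohort plus three auxiliary datasets (a smaller,
resolver-dominated trauma cohort measured on a reduced panel, and two
severity cohorts), mirroring the cross-platform structure the score
construction expects.
"""

from __future__ import annotations

from typing import Tuple

from .config import CovidGenConfig, PlantedTruth, TraumaGenConfig
from .covid import generate_covid_cohort
from .trauma import generate_trauma_cohort

__all__ = ["secondary_trauma_config", "secondary_covid_config",
           "generate_reference_suite"]


def secondary_trauma_config() -> TraumaGenConfig:
    """Smaller validation-style trauma cohort: resolver-dominated, single
    arm, reduced untargeted-style panel (no TAG/LPC/LPE/DCER)."""
    return TraumaGenConfig(
        n_per_cell={("resolving", "standard_care"): 45,
                    ("non_resolving", "standard_care"): 20,
                    ("early_nonsurvivor", "standard_care"): 3},
        n_healthy=10,
        species_counts={"PE": 30, "PC": 20, "DAG": 15, "MAG": 6, "SM": 10,
                        "CER": 8, "PI": 6, "CE": 4, "HCER": 3, "LCER": 3},
        planted_other_counts={"DAG": 4, "CER": 2},
        planted_down_count=0,
    )


def secondary_covid_config() -> CovidGenConfig:
    """Smaller second severity cohort."""
    return CovidGenConfig(n_healthy=5, n_non_severe=20, n_severe=15)


def generate_reference_suite(seed: int):
    """Generate the four-dataset suite.

    Returns ``(matrix, cohort, truth, aux)`` where ``aux`` is the list of
    auxiliary dataset descriptors consumed by
    :func:`lipidscore.pipeline.build_lrs`.
    """
    matrix, cohort, truth = generate_trauma_cohort(TraumaGenConfig(), seed)
    m2, c2, _ = generate_trauma_cohort(secondary_trauma_config(),
                                       20_000 + seed)
    cm1, cc1, _ = generate_covid_cohort(CovidGenConfig(), 10_000 + seed)
    cm2, cc2, _ = generate_covid_cohort(secondary_covid_config(),
                                        30_000 + seed)
    aux = [
        {"id": "trauma2", "kind": "trauma", "matrix": m2, "cohort": c2.table},
        {"id": "severity1", "kind": "severity", "matrix": cm1,
         "cohort": cc1.table},
        {"id": "severity2", "kind": "severity", "matrix": cm2,
         "cohort": cc2.table},
    ]
    return matrix, cohort, truth, aux
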