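import numpy as np
import pandas as pd
import pytest

from lipidscore.data import CohortTable, LipidomicsMatrix
from lipidscore.simulate import (CovidGenConfig, TraumaGenConfig,
                                 generate_covid_cohort, generate_trauma_cohort)


@pytest.fixture
def tiny_matrix():
    """4 samples x 4 species, no missing values."""
    values = pd.DataFrame(
        {
            "PE(16:0_18:2)": [1.0, 2.0, 3.0, 4.0],
            "PE(16:0_20:4)": [2.0, 2.5, 3.0, 3.5],
            "TAG(16:0_18:1_18:2)": [10.0, 12.0, 9.0, 11.0],
            "CE(18:1)": [5.0, 5.5, 6.0, 6.5],
        },
        index=["s1", "s2", "s3", "s4"],
    )
    return LipidomicsMatrix(values, dataset_id="tiny")


@pytest.fixture
def missing_matrix():
    """10 samples; species with 0, 2 and 3 missing cells."""
    rng = np.random.default_rng(0)
    idx = [f"s{i}" for i in range(10)]
    values = pd.DataFrame(
        {
            "PE(16:0_18:2)": rng.uniform(1, 5, 10),
            "PC(16:0_18:1)": rng.uniform(1, 5, 10),
            "CE(18:1)": rng.uniform(1, 5, 10),
        },
        index=idx,
    )
    values.iloc[[0, 1], 1] = np.nan          # 2/10 missing
    values.iloc[[0, 1, 2], 2] = np.nan       # 3/10 missing
    return LipidomicsMatrix(values, dataset_id="missing")


@pytest.fixture(scope="session")
def small_trauma_cfg():
    """Scaled-down trauma generator config for fast unit tests."""
    return TraumaGenConfig(
        n_per_cell={
            ("resolving", "standard_care"): 15, ("resolving", "TP"): 15,
            ("non_resolving", "standard_care"): 15, ("non_resolving", "TP"): 15,
            ("early_nonsurvivor", "standard_care"): 10,
            ("early_nonsurvivor", "TP"): 10,
        },
        n_healthy=10,
        species_counts={"TAG": 40, "PE": 20, "PC": 15, "DAG": 12, "LPC": 8,
                        "CER": 8, "SM": 6, "MAG": 4, "PI": 4, "LPE": 4,
                        "HCER": 3, "LCER": 3, "DCER": 3, "CE": 3},
        planted_other_counts={"TAG": 6, "DAG": 3, "CER": 2},
    )


@pytest.fixture(scope="session")
def small_trauma(small_trauma_cfg):
    return generate_trauma_cohort(small_trauma_cfg, seed=11)


@pytest.fixture(scope="session")
def small_covid():
    return generate_covid_cohort(CovidGenConfig(), seed=12)
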