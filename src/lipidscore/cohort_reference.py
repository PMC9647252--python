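"""Published cohort summary counts used for worked-example cross-checks.

These are the printed group-level counts and arm-level 30-day mortality
proportions from the source trial's demographic table; they serve as fixed
inputs for percentage arithmetic, not as fitted quantities.
"""

from __future__ import annotations

__all__ = [
    "OUTCOME_GROUP_SIZES", "MOF_COUNTS", "ARM_COUNTS", "ARM_MORTALITY_PCT",
    "percentage", "mortality_difference_pp",
]

#: Patients per outcome group.
OUTCOME_GROUP_SIZES = {
    "healthy": 17,
    "resolving": 41,
    "non_resolving": 101,
    "early_nonsurvivor": 51,
}

#: Patients meeting multiple-organ-failure criteria, by outcome group.
MOF_COUNTS = {
    "resolving": 31,
    "non_resolving": 98,
}

#: Randomization arm counts by outcome group.
ARM_COUNTS = {
    "resolving": {"standard_care": 25, "TP": 16},
    "non_resolving": {"standard_care": 48, "TP": 53},
    "early_nonsurvivor": {"standard_care": 36, "TP": 15},
}

#: 30-day mortality (%) by randomization arm in the full trial.
ARM_MORTALITY_PCT = {"TP": 23.2, "standard_care": 33.0}


def percentage(count: int, total: int, ndigits: int = 1) -> float:
    """``count / total`` expressed as a percentage, rounded."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, ndigits)


def mortality_difference_pp() -> float:
    """Treatment-arm minus standard-care 30-day mortality, percentage points."""
    return round(ARM_MORTALITY_PCT["TP"] - ARM_MORTALITY_PCT["standard_care"], 1)
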