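"""Risk-group taxonomy and design-matrix construction.

Colombian capitation regulation adjusts the premium over 56 risk cells:
4 geographic regions crossed with 14 age/sex categories.  Both marginal
GLMs share the same linear predictor built from region and age/sex main
effects with reference-cell dummy coding, baseline ``(normal, <1y)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

REGIONS: tuple[str, ...] = ("normal", "remote", "cities", "special")

AGE_SEX: tuple[str, ...] = (
    "<1y",
    "1-4",
    "5-14",
    "15-18M",
    "15-18F",
    "19-44M",
    "19-44F",
    "45-49",
    "50-54",
    "55-59",
    "60-64",
    "65-69",
    "70-74",
    ">=75",
)

#: number of linear-predictor coefficients: intercept + 3 region + 13 age/sex dummies
N_COEF = 1 + (len(REGIONS) - 1) + (len(AGE_SEX) - 1)


@dataclass(frozen=True, order=True)
class RiskGroup:
    """One of the 56 region x age/sex risk cells."""

    region: str
    age_sex: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.age_sex not in AGE_SEX:
            raise ValueError(f"unknown age/sex category {self.age_sex!r}")

    @property
    def index(self) -> int:
        """Stable integer index 0..55, region-major then age/sex."""
        return REGIONS.index(self.region) * len(AGE_SEX) + AGE_SEX.index(self.age_sex)


def enumerate_groups() -> list[RiskGroup]:
    """All 56 risk groups in fixed region-major, then age/sex order."""
    return [RiskGroup(r, a) for r in REGIONS for a in AGE_SEX]


def design_row(group: RiskGroup) -> np.ndarray:
    """Reference-cell dummy encoding of one group (baseline: normal, <1y)."""
    row = np.zeros(N_COEF)
    row[0] = 1.0
    ir = REGIONS.index(group.region)
    if ir > 0:
        row[ir] = 1.0
    ia = AGE_SEX.index(group.age_sex)
    if ia > 0:
        row[len(REGIONS) - 1 + ia] = 1.0
    return row


def design_matrix(groups: list[RiskGroup] | pd.DataFrame) -> np.ndarray:
    """Stack design rows for a list of groups or a panel frame.

    Accepts either a list of :class:`RiskGroup` or a DataFrame with
    ``region`` and ``age_sex`` columns (one row per record).
    """
    if isinstance(groups, pd.DataFrame):
        groups = [RiskGroup(r, a) for r, a in zip(groups["region"], groups["age_sex"])]
    return np.array([design_row(g) for g in groups])


def coef_names() -> list[str]:
    """Names of the 17 linear-predictor coefficients, matching design_row order."""
    return (
        ["intercept"]
        + [f"region[{r}]" for r in REGIONS[1:]]
        + [f"age_sex[{a}]" for a in AGE_SEX[1:]]
    )
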