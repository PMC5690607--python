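"""Species trait tables and Red List status dichotomization.

The response modelled throughout the package is the dichotomous Red List
status: species assessed Vulnerable, Endangered, Critically Endangered,
Extinct in the Wild or Extinct are "at risk"; Near Threatened and Least
Concern species are "not at risk"; Data Deficient species carry no label
and are scored by the fitted model instead of training it.
"""

from __future__ import annotations

import enum

import numpy as np
import pandas as pd

__all__ = [
    "REDLIST_CODES",
    "AT_RISK_CODES",
    "NOT_AT_RISK_CODES",
    "RiskLabel",
    "dichotomize_status",
    "dichotomize_series",
    "read_trait_table",
    "write_trait_table",
]

REDLIST_CODES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD")
AT_RISK_CODES = frozenset({"VU", "EN", "CR", "EW", "EX"})
NOT_AT_RISK_CODES = frozenset({"LC", "NT"})

#: numeric trait columns of the canonical table
NUMERIC_TRAITS = (
    "body_mass",
    "range_size",
    "mass_specific_production",
    "social_group_size",
    "home_range",
    "population_density",
)
#: categorical trait columns of the canonical table
CATEGORICAL_TRAITS = (
    "order_name",
    "trophic_group",
    "activity_cycle",
    "habitat_mode",
    "landmass_type",
)

REQUIRED_COLUMNS = ("species_id", "redlist_status")


class RiskLabel(enum.Enum):
    AT_RISK = "at_risk"
    NOT_AT_RISK = "not_at_risk"
    UNLABELED = "unlabeled"


def dichotomize_status(status: str) -> RiskLabel:
    """Map an IUCN Red List code to the binary risk response.

    VU/EN/CR/EW/EX -> at risk; NT/LC -> not at risk; DD -> unlabeled.
    Any other code is rejected.
    """
    if status in AT_RISK_CODES:
        return RiskLabel.AT_RISK
    if status in NOT_AT_RISK_CODES:
        return RiskLabel.NOT_AT_RISK
    if status == "DD":
        return RiskLabel.UNLABELED
    raise ValueError(f"unknown Red List status code: {status!r}")


def dichotomize_series(statuses: pd.Series) -> pd.Series:
    """Vectorized dichotomization: 1.0 at risk, 0.0 not at risk, NaN for DD."""
    out = pd.Series(np.nan, index=statuses.index, dtype=float)
    for code in statuses.dropna().unique():
        dichotomize_status(code)  # raises on unknown codes, naming them
    out[statuses.isin(AT_RISK_CODES)] = 1.0
    out[statuses.isin(NOT_AT_RISK_CODES)] = 0.0
    return out


def read_trait_table(path) -> pd.DataFrame:
    """Read a species trait table from CSV.

    Empty cells become NaN and are preserved as missing throughout the
    package (no imputation anywhere).  ``species_id`` must be present and
    unique; ``redlist_status`` must be present.
    """
    df = pd.read_csv(path, dtype={"species_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"trait table is missing required column {col!r}")
    dupes = df["species_id"][df["species_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate species_id in trait table: {sorted(set(dupes))}")
    for col in NUMERIC_TRAITS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
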