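"""Reading and writing cohort tables and derived artifacts.

The cohort CSV dialect: one header row; the 19 canonical disease columns plus
hospitalised, readmissions, length_of_stay, sex, age_group, survey_weight;
empty cells denote missing values. Binary fields accept 0/1 as well as a
documented recode map (yes/no, true/false). Unknown columns are preserved
as passthrough.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    AGE_GROUP,
    AGE_GROUPS,
    DISEASES,
    HOSPITALISED,
    REQUIRED_COLUMNS,
    SEX,
    SEXES,
    SURVEY_WEIGHT,
)

#: Accepted spellings for binary cells, besides 0/1.
BINARY_RECODE = {
    "yes": 1.0, "no": 0.0,
    "true": 1.0, "false": 0.0,
    "1": 1.0, "0": 0.0, "1.0": 1.0, "0.0": 0.0,
}

_BINARY_COLUMNS = DISEASES + (HOSPITALISED,)


def _recode_binary(series: pd.Series, column: str) -> pd.Series:
    def convert(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, str):
            key = v.strip().lower()
            if key == "":
                return np.nan
            if key in BINARY_RECODE:
                return BINARY_RECODE[key]
            raise ValueError(f"non-binary value {v!r} in column {column!r}")
        if v in (0, 1, 0.0, 1.0):
            return float(v)
        raise ValueError(f"non-binary value {v!r} in column {column!r}")

    return series.map(convert).astype(float)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Load and validate a person-level cohort table."""
    df = pd.read_csv(path, dtype={SEX: str, AGE_GROUP: str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing mandatory column(s): {missing}")
    for col in _BINARY_COLUMNS:
        try:
            df[col] = _recode_binary(df[col], col)
        except ValueError as e:
            bad = df[col].map(
                lambda v: not (pd.isna(v) or str(v).strip().lower() in BINARY_RECODE
                               or v in (0, 1, 0.0, 1.0))
            )
            row = int(np.argmax(bad.to_numpy())) if bad.any() else -1
            raise ValueError(f"{e} (first offending row: {row})") from None
    bad_sex = ~df[SEX].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"unknown sex value(s): {sorted(df.loc[bad_sex, SEX].unique())}")
    bad_age = ~df[AGE_GROUP].isin(AGE_GROUPS)
    if bad_age.any():
        raise ValueError(
            f"unknown age_group value(s): {sorted(df.loc[bad_age, AGE_GROUP].unique())}"
        )
    if (df[SURVEY_WEIGHT] <= 0).any():
        raise ValueError("survey_weight must be positive")
    return df


def write_cohort_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table; missing values become empty cells."""
    table.to_csv(path, index=False, na_rep="")
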