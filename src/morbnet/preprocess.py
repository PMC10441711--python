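"""Complete-case extraction, IPW weights, multimorbidity flags, stratification.

The analysis sample is the set of rows with complete data on all variables of
interest. To keep complete-case estimates representative under a
missing-at-random mechanism, each complete case is reweighted by the inverse
of its modelled probability of being complete (inverse probability weighting,
IPW), multiplied into the survey weight. The completeness model is a logistic
regression on the always-observed covariates sex and age group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import (
    AGE_GROUP,
    AGE_GROUPS,
    DISEASES,
    HOSPITALISED,
    SEX,
    SEXES,
    SURVEY_WEIGHT,
)

logger = logging.getLogger(__name__)

#: Variables whose completeness defines the analysis sample.
ANALYSIS_VARIABLES: tuple[str, ...] = DISEASES + (HOSPITALISED,)


@dataclass
class AnalysisWeights:
    """Per-person weights for complete cases.

    combined_weight = survey_weight / completeness_prob, rescaled to unit
    mean over complete cases (prevalence ratios and regression coefficients
    are invariant to the rescaling; it keeps effective sample sizes honest).
    """

    index: pd.Index  # rows of the complete-case table these weights belong to
    survey_weight: np.ndarray
    completeness_prob: np.ndarray
    combined_weight: np.ndarray

    def __post_init__(self):
        if np.any(self.completeness_prob <= 0) or np.any(self.completeness_prob > 1):
            raise ValueError("completeness probabilities must lie in (0, 1]")


def complete_cases(table: pd.DataFrame, variables: tuple[str, ...] = ANALYSIS_VARIABLES) -> pd.DataFrame:
    """Rows with complete data for every analysis variable."""
    keep = table[list(variables)].notna().all(axis=1)
    dropped = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"no complete cases: all {len(table)} rows have missing analysis variables"
        )
    if dropped:
        logger.info("complete_cases: dropped %d of %d rows", dropped, len(table))
    return table.loc[keep]


def fit_ipw_weights(full_table: pd.DataFrame) -> AnalysisWeights:
    """Fit the completeness model on ALL rows and weight the complete cases.

    Completeness ~ logistic(sex + age_group), fitted by maximum likelihood on
    the full table (complete and incomplete rows alike). Raises if any
    sex x age stratum has no complete rows (the model would separate and the
    corresponding weights diverge).
    """
    complete = full_table[list(ANALYSIS_VARIABLES)].notna().all(axis=1)
    for sex in SEXES:
        for age in AGE_GROUPS:
            in_stratum = (full_table[SEX] == sex) & (full_table[AGE_GROUP] == age)
            if in_stratum.any() and not complete[in_stratum].any():
                raise ValueError(
                    f"stratum ({sex}, {age}) has no complete cases; "
                    "completeness model would separate"
                )
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "male": (full_table[SEX] == "male").astype(float),
            "age_60_74": (full_table[AGE_GROUP] == AGE_GROUPS[1]).astype(float),
            "age_75": (full_table[AGE_GROUP] == AGE_GROUPS[2]).astype(float),
        }
    )
    model = sm.GLM(complete.astype(float), X, family=sm.families.Binomial())
    probs = np.asarray(model.fit().predict(X))

    idx = full_table.index[complete]
    sw = full_table.loc[idx, SURVEY_WEIGHT].to_numpy(float)
    cp = probs[complete.to_numpy()]
    combined = sw / cp
    combined = combined / combined.mean()
    return AnalysisWeights(
        index=idx, survey_weight=sw, completeness_prob=cp, combined_weight=combined
    )


def classify_mm(table: pd.DataFrame) -> pd.DataFrame:
    """Condition counts and the two multimorbidity definitions.

    mm2: at least two of the 19 conditions; mm3: at least three. mm3 cases
    are by construction a subset of mm2 cases.
    """
    block = table[list(DISEASES)]
    if block.isna().any().any():
        raise ValueError("disease block contains missing values; run complete_cases first")
    count = block.sum(axis=1).astype(int)
    return pd.DataFrame(
        {"condition_count": count, "mm2": count >= 2, "mm3": count >= 3},
        index=table.index,
    )


def stratify(table: pd.DataFrame, by: str) -> dict[str, pd.DataFrame]:
    """Named sub-tables by sex, age group, their crossing, or an MM filter.

    'sex', 'age_group' and 'sex_age' partition the table exactly; 'mm2' and
    'mm3' return a single filtered subset.
    """
    if by == "sex":
        return {s: table[table[SEX] == s] for s in SEXES}
    if by == "age_group":
        return {a: table[table[AGE_GROUP] == a] for a in AGE_GROUPS}
    if by == "sex_age":
        return {
            f"{s}_{a}": table[(table[SEX] == s) & (table[AGE_GROUP] == a)]
            for s in SEXES
            for a in AGE_GROUPS
        }
    if by in ("mm2", "mm3"):
        flags = classify_mm(table)[by]
        return {by: table[flags]}
    raise KeyError(f"unknown stratification key: {by!r}")
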