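"""Survey-weighted outcome regressions.

Hospitalisation (binary) is modelled with log-link Poisson regression so the
exponentiated coefficients are prevalence ratios (PR); because the Poisson
variance misspecifies a Bernoulli outcome, inference uses the weighted
sandwich covariance

    V = B^{-1} M B^{-1},   B = sum_i w_i mu_i x_i x_i',
                           M = sum_i w_i^2 (y_i - mu_i)^2 x_i x_i',

which is consistent under the working-model misspecification. Readmission
counts and length of stay (among hospitalised persons) use weighted least
squares with heteroscedasticity-robust (HC1) standard errors. All fits take
the combined survey x IPW weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .catalog import AGE_GROUP, AGE_GROUPS, HOSPITALISED, LENGTH_OF_STAY, READMISSIONS, SEX, SEXES

Z95 = 1.959963984540054  # standard normal 97.5% quantile

#: covariate name -> (column, ordered levels); first level is the reference
COVARIATE_LEVELS = {
    "sex": (SEX, list(SEXES)),
    "age_group": (AGE_GROUP, list(AGE_GROUPS)),
}


@dataclass
class RegressionResult:
    outcome: str
    subset: str  # mm2 | mm3 | all
    stratum: str  # e.g. "all", "female", "male"
    term: str  # covariate level, e.g. "sex=male"
    estimate: float  # PR for hospitalisation, beta otherwise
    ci_low: float
    ci_high: float
    reference: bool
    reference_level: str

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence bounds must bracket the estimate")


def _build_design(
    table: pd.DataFrame, covariates: list[str]
) -> tuple[np.ndarray, list[tuple[str, str]], list[tuple[str, str]]]:
    """Dummy-coded design with intercept; empty levels dropped with a warning.

    Returns (X, terms, references): terms are (covariate, level) per non-
    reference column, references the (covariate, reference level) pairs.
    """
    cols = [np.ones(len(table))]
    terms: list[tuple[str, str]] = []
    refs: list[tuple[str, str]] = []
    for cov in covariates:
        col, levels = COVARIATE_LEVELS[cov]
        present = [lv for lv in levels if (table[col] == lv).any()]
        if len(present) < 2:
            warnings.warn(
                f"covariate {cov!r} has a single occupied level in this subset; dropped"
            )
            continue
        refs.append((cov, present[0]))
        for lv in present[1:]:
            cols.append((table[col] == lv).to_numpy(float))
            terms.append((cov, lv))
    return np.column_stack(cols), terms, refs


def _poisson_sandwich_cov(X: np.ndarray, y: np.ndarray, w: np.ndarray, beta: np.ndarray) -> np.ndarray:
    mu = np.exp(X @ beta)
    B = X.T @ (X * (w * mu)[:, None])
    resid = w * (y - mu)
    M = X.T @ (X * (resid**2)[:, None])
    Binv = np.linalg.inv(B)
    return Binv @ M @ Binv


def fit_weighted_poisson_pr(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    weights: np.ndarray,
    subset: str = "all",
    stratum: str = "all",
) -> list[RegressionResult]:
    """Prevalence ratios from weighted log-link Poisson with robust variance."""
    y = table[outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"outcome {outcome!r} must be binary for prevalence ratios")
    X, terms, refs = _build_design(table, covariates)
    w = np.asarray(weights, dtype=float)
    model = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w)
    fit = model.fit(maxiter=200, tol=1e-10)
    if not fit.converged:
        raise RuntimeError(
            f"Poisson fit did not converge (outcome={outcome}, stratum={stratum})"
        )
    beta = np.asarray(fit.params)
    cov = _poisson_sandwich_cov(X, y, w, beta)
    se = np.sqrt(np.diag(cov))

    results = []
    for cov_name, ref_level in refs:
        results.append(
            RegressionResult(outcome, subset, stratum, f"{cov_name}={ref_level}",
                             1.0, 1.0, 1.0, True, ref_level)
        )
    ref_of = dict(refs)
    for k, (cov_name, level) in enumerate(terms, start=1):
        results.append(
            RegressionResult(
                outcome, subset, stratum, f"{cov_name}={level}",
                float(np.exp(beta[k])),
                float(np.exp(beta[k] - Z95 * se[k])),
                float(np.exp(beta[k] + Z95 * se[k])),
                False, ref_of[cov_name],
            )
        )
    return results


def fit_weighted_linear(
    table: pd.DataFrame,
    outcome: str,
    covariates: list[str],
    weights: np.ndarray,
    subset: str = "all",
    stratum: str = "all",
    robust: bool = True,
) -> list[RegressionResult]:
    """Weighted least squares with HC1 (or classical) standard errors."""
    y = table[outcome].to_numpy(float)
    X, terms, refs = _build_design(table, covariates)
    if len(y) <= X.shape[1]:
        raise ValueError(
            f"n={len(y)} too small for {X.shape[1]} design columns (outcome={outcome})"
        )
    w = np.asarray(weights, dtype=float)
    fit = sm.WLS(y, X, weights=w).fit(cov_type="HC1" if robust else "nonrobust")
    beta = np.asarray(fit.params)
    se = np.asarray(fit.bse)

    results = []
    for cov_name, ref_level in refs:
        results.append(
            RegressionResult(outcome, subset, stratum, f"{cov_name}={ref_level}",
                             0.0, 0.0, 0.0, True, ref_level)
        )
    ref_of = dict(refs)
    for k, (cov_name, level) in enumerate(terms, start=1):
        results.append(
            RegressionResult(
                outcome, subset, stratum, f"{cov_name}={level}",
                float(beta[k]),
                float(beta[k] - Z95 * se[k]),
                float(beta[k] + Z95 * se[k]),
                False, ref_of[cov_name],
            )
        )
    return results


def run_regression_suite(
    table: pd.DataFrame,
    weights: np.ndarray,
    mm_flags: pd.DataFrame,
    readmission_family: str = "linear",
) -> list[RegressionResult]:
    """The full outcome-association grid.

    For each multimorbidity subset (mm2, mm3) and each outcome, fits
    (a) the joint sex + age-group model, (b) age group within females, and
    (c) age group within males. Hospitalisation uses the Poisson PR model on
    the subset; readmission and length of stay use weighted linear models on
    the hospitalised members of the subset (Poisson available for
    readmissions via ``readmission_family='poisson'``).
    """
    w = pd.Series(np.asarray(weights, float), index=table.index)
    results: list[RegressionResult] = []
    for subset in ("mm2", "mm3"):
        sub = table[mm_flags[subset]]
        strata = {
            "all": (sub, ["sex", "age_group"]),
            "female": (sub[sub[SEX] == "female"], ["age_group"]),
            "male": (sub[sub[SEX] == "male"], ["age_group"]),
        }
        for stratum, (t, covs) in strata.items():
            results += fit_weighted_poisson_pr(
                t, HOSPITALISED, covs, w.loc[t.index].to_numpy(), subset, stratum
            )
            hosp = t[t[HOSPITALISED] == 1]
            wh = w.loc[hosp.index].to_numpy()
            if readmission_family == "poisson":
                # counts are >= 1 by convention; model the excess over 1
                shifted = hosp.assign(**{READMISSIONS: hosp[READMISSIONS]})
                results += _poisson_count_fit(shifted, READMISSIONS, covs, wh, subset, stratum)
            else:
                results += fit_weighted_linear(hosp, READMISSIONS, covs, wh, subset, stratum)
            results += fit_weighted_linear(hosp, LENGTH_OF_STAY, covs, wh, subset, stratum)
    return results


def _poisson_count_fit(table, outcome, covariates, weights, subset, stratum):
    y = table[outcome].to_numpy(float)
    X, terms, refs = _build_design(table, covariates)
    fit = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=np.asarray(weights, float)).fit()
    beta = np.asarray(fit.params)
    cov = _poisson_sandwich_cov(X, y, np.asarray(weights, float), beta)
    se = np.sqrt(np.diag(cov))
    out = [
        RegressionResult(outcome, subset, stratum, f"{c}={r}", 1.0, 1.0, 1.0, True, r)
        for c, r in refs
    ]
    ref_of = dict(refs)
    for k, (c, lv) in enumerate(terms, start=1):
        out.append(
            RegressionResult(
                outcome, subset, stratum, f"{c}={lv}",
                float(np.exp(beta[k])),
                float(np.exp(beta[k] - Z95 * se[k])),
                float(np.exp(beta[k] + Z95 * se[k])),
                False, ref_of[c],
            )
        )
    return out


def results_to_frame(results: list[RegressionResult]) -> pd.DataFrame:
    """Tidy one-row-per-term table of a result set."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome, "subset": r.subset, "stratum": r.stratum,
                "term": r.term, "estimate": r.estimate,
                "ci_low": r.ci_low, "ci_high": r.ci_high,
                "reference": r.reference, "reference_level": r.reference_level,
            }
            for r in results
        ]
    )


def format_results_table(results: list[RegressionResult]) -> str:
    """Plain-text rendering grouped like the published association tables."""
    df = results_to_frame(results)
    lines = []
    for (subset, outcome), grp in df.groupby(["subset", "outcome"], sort=False):
        kind = "PR" if outcome == HOSPITALISED else "beta"
        lines.append(f"== {outcome} | multimorbidity subset: {subset} ==")
        for stratum, g in grp.groupby("stratum", sort=False):
            lines.append(f"  [{stratum}]")
            for _, r in g.iterrows():
                if r.reference:
                    lines.append(f"    {r.term:24s} {kind} = 1.00 (reference)"
                                 if kind == "PR" else
                                 f"    {r.term:24s} {kind} = 0.00 (reference)")
                else:
                    lines.append(
                        f"    {r.term:24s} {kind} = {r.estimate:6.2f} "
                        f"({r.ci_low:.2f}, {r.ci_high:.2f})"
                    )
        lines.append("")
    return "\n".join(lines)
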