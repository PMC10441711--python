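"""Synthetic cohorts with known ground truth.

Generates analysis-ready person-level tables that emulate the structure of a
national ageing-cohort survey of adults aged 50+: 19 self-reported chronic
conditions drawn from a pairwise Ising model (so the conditional dependence
graph is known exactly), hospitalisation / readmission / length-of-stay
outcomes linked to the conditions through generalised-linear predictors,
survey weights, and missing-at-random (MAR) incompleteness driven only by the
always-observed covariates sex and age group.

Disease indicators are coded {0,1} throughout (not +/-1), matching the
logistic conditionals the nodewise estimator uses:

    P(x_i = 1 | x_-i) = logistic(tau_i + sum_j w_ij x_j).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .catalog import (
    AGE_GROUP,
    AGE_GROUPS,
    DISEASES,
    HOSPITALISED,
    LENGTH_OF_STAY,
    MASKABLE_COLUMNS,
    N_DISEASES,
    READMISSIONS,
    SEX,
    SEXES,
    SURVEY_WEIGHT,
)

#: Covariates a MAR missingness model may reference (always observed).
MISSING_MODEL_TERMS = ("intercept", "male", "age_60_74", "age_75")


class InvalidModelError(ValueError):
    """Raised for malformed Ising parameters (asymmetry, nonzero diagonal)."""


def _check_ising_params(weights: np.ndarray, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    weights = np.asarray(weights, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    p = len(thresholds)
    if weights.shape != (p, p):
        raise InvalidModelError(f"weights must be {p}x{p}, got {weights.shape}")
    if not np.allclose(weights, weights.T):
        raise InvalidModelError("coupling matrix must be symmetric")
    if np.any(np.diag(weights) != 0):
        raise InvalidModelError("coupling matrix must have zero diagonal")
    return weights, thresholds


def enumerate_ising(weights: np.ndarray, thresholds: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All 2^p states and their exact probabilities.

    P(x) is proportional to exp(sum_i tau_i x_i + sum_{i<j} w_ij x_i x_j).
    Only feasible for small p; the exact sampler enforces p <= 16.
    """
    weights, thresholds = _check_ising_params(weights, thresholds)
    p = len(thresholds)
    states = ((np.arange(2**p)[:, None] >> np.arange(p)) & 1).astype(float)
    energy = states @ thresholds + 0.5 * np.einsum("si,ij,sj->s", states, weights, states)
    energy -= energy.max()
    probs = np.exp(energy)
    probs /= probs.sum()
    return states, probs


def sample_ising_exact(
    weights: np.ndarray, thresholds: np.ndarray, n: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """n iid draws from the Ising model by exact state enumeration (p <= 16)."""
    p = len(np.asarray(thresholds))
    if p > 16:
        raise ValueError(f"p={p} > 16: exact enumeration infeasible, use sample_ising_gibbs")
    states, probs = enumerate_ising(weights, thresholds)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(states), size=n, p=probs)
    return states[idx]


def sample_ising_gibbs(
    weights: np.ndarray,
    thresholds: np.ndarray,
    n: int,
    burn_in: int = 1000,
    thin: int = 10,
    seed: int | np.random.Generator = 0,
    n_chains: int = 512,
) -> np.ndarray:
    """Gibbs sampling from the Ising model, scalable to any p.

    Runs `n_chains` independent chains in parallel (each updated by
    systematic single-site scans with conditional probability
    logistic(tau_i + sum_j w_ij x_j)), discards `burn_in` full sweeps, then
    records every chain's state every `thin` sweeps until n rows are
    collected. Parallel chains make the draws closer to iid than a single
    thinned chain of the same budget while keeping the update fully
    vectorised.
    """
    weights, thresholds = _check_ising_params(weights, thresholds)
    if burn_in < 0 or thin < 1:
        raise ValueError("burn_in must be >= 0 and thin >= 1")
    if n <= 0:
        raise ValueError("n must be positive")
    p = len(thresholds)
    rng = np.random.default_rng(seed)
    m = min(n, n_chains)
    state = (rng.random((m, p)) < expit(thresholds)).astype(float)

    def sweep():
        for i in range(p):
            cond = expit(thresholds[i] + state @ weights[:, i])
            state[:, i] = (rng.random(m) < cond).astype(float)

    for _ in range(burn_in):
        sweep()
    out = np.empty((n, p))
    filled = 0
    while filled < n:
        for _ in range(thin):
            sweep()
        take = min(m, n - filled)
        out[filled : filled + take] = state[:take]
        filled += take
    return out


@dataclass
class OutcomeModel:
    """Linear predictor on disease indicators plus sex/age terms."""

    intercept: float
    disease_coefs: np.ndarray  # length 19, canonical disease order
    male: float = 0.0
    age_60_74: float = 0.0
    age_75: float = 0.0

    def linear_predictor(self, X: np.ndarray, male: np.ndarray, age_idx: np.ndarray) -> np.ndarray:
        return (
            self.intercept
            + X @ self.disease_coefs
            + self.male * male
            + self.age_60_74 * (age_idx == 1)
            + self.age_75 * (age_idx == 2)
        )

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "disease_coefs": list(np.asarray(self.disease_coefs, dtype=float)),
            "male": self.male,
            "age_60_74": self.age_60_74,
            "age_75": self.age_75,
        }


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover.

    Thresholds are for the reference stratum (female, 50-59); `sex_shift` is
    added for males and `age_shift` once per age band above the youngest,
    all on the log-odds scale.
    """

    edge_weights: np.ndarray  # (19, 19) symmetric, zero diagonal
    thresholds: np.ndarray  # (19,)
    outcome_coeffs: dict[str, OutcomeModel]
    community_labels: dict[str, int]
    missing_model: dict[str, float]
    sex_shift: np.ndarray = field(default_factory=lambda: np.zeros(N_DISEASES))
    age_shift: np.ndarray = field(default_factory=lambda: np.zeros(N_DISEASES))
    los_shape: float = 1.5  # Gamma shape of the length-of-stay noise model
    seed: int | None = None

    def __post_init__(self):
        self.edge_weights, self.thresholds = _check_ising_params(self.edge_weights, self.thresholds)
        labelled = set(self.community_labels)
        if labelled != set(DISEASES):
            raise ValueError("community_labels must partition the 19 conditions")
        bad = set(self.missing_model) - set(MISSING_MODEL_TERMS)
        if bad:
            raise ValueError(f"missing_model may only use always-observed covariates, got {sorted(bad)}")

    def stratum_thresholds(self, sex: str, age_idx: int) -> np.ndarray:
        tau = self.thresholds.copy()
        if sex == "male":
            tau = tau + self.sex_shift
        return tau + age_idx * self.age_shift

    def true_edges(self, tol: float = 0.0) -> set[tuple[int, int]]:
        """Index pairs (i<j) of planted nonzero couplings."""
        p = self.edge_weights.shape[0]
        return {
            (i, j)
            for i in range(p)
            for j in range(i + 1, p)
            if abs(self.edge_weights[i, j]) > tol
        }

    def to_json(self, path: str | Path) -> None:
        payload = {
            "diseases": list(DISEASES),
            "edge_weights": self.edge_weights.tolist(),
            "thresholds": self.thresholds.tolist(),
            "sex_shift": self.sex_shift.tolist(),
            "age_shift": self.age_shift.tolist(),
            "outcome_coeffs": {k: v.to_dict() for k, v in self.outcome_coeffs.items()},
            "community_labels": self.community_labels,
            "missing_model": self.missing_model,
            "los_shape": self.los_shape,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


# ----------------------------------------------------------------------------
# Default scenario: an ELSI-like cohort of Brazilians aged 50+
# ----------------------------------------------------------------------------

#: Overall target marginal prevalences used to centre the thresholds
#: (reference values chosen to mimic a 50+ household survey: hypertension and
#: back problems very common, neurodegenerative disease rare).
_TARGET_PREV = np.array(
    [0.52, 0.41, 0.30, 0.30, 0.25, 0.22, 0.17, 0.14, 0.12, 0.06,
     0.05, 0.04, 0.05, 0.05, 0.035, 0.03, 0.025, 0.01, 0.015]
)

#: Planted community structure: cardiovascular-cancer-eye, musculoskeletal-
#: depression-renal, diabetes and complications, respiratory, and
#: neurodegenerative groups.
_COMMUNITIES = {
    "hypertension": 0, "heart_problems": 0, "haemorrhagic_stroke": 0,
    "cancer": 0, "cataract": 0, "glaucoma": 0, "macular_degeneration": 0,
    "back_problems": 1, "arthritis_rheumatism": 1, "osteoporosis": 1,
    "depression": 1, "renal_failure": 1,
    "diabetes": 2, "high_cholesterol": 2, "diabetic_retinopathy": 2,
    "copd": 3, "asthma": 3,
    "parkinsons": 4, "alzheimers": 4,
}

#: Within-community couplings (chains plus a few chords) and weaker
#: between-community bridges, on the log-odds interaction scale.
_EDGES = [
    # cardiovascular / cancer / eye
    ("hypertension", "heart_problems", 0.9),
    ("heart_problems", "haemorrhagic_stroke", 0.8),
    ("hypertension", "haemorrhagic_stroke", 0.5),
    ("heart_problems", "cancer", 0.5),
    ("cataract", "glaucoma", 0.9),
    ("cataract", "macular_degeneration", 0.7),
    ("hypertension", "cataract", 0.4),
    ("cancer", "cataract", 0.4),
    # musculoskeletal / depression / renal
    ("back_problems", "arthritis_rheumatism", 0.9),
    ("arthritis_rheumatism", "osteoporosis", 0.8),
    ("back_problems", "depression", 0.6),
    ("depression", "renal_failure", 0.6),
    ("osteoporosis", "depression", 0.4),
    # diabetes cluster
    ("diabetes", "high_cholesterol", 0.7),
    ("diabetes", "diabetic_retinopathy", 1.4),
    ("high_cholesterol", "diabetic_retinopathy", 0.3),
    # respiratory
    ("copd", "asthma", 1.1),
    # neurodegenerative
    ("parkinsons", "alzheimers", 1.5),
    # bridges
    ("hypertension", "diabetes", 0.35),
    ("hypertension", "high_cholesterol", 0.35),
    ("haemorrhagic_stroke", "alzheimers", 0.5),
    ("depression", "alzheimers", 0.4),
]


def _vec(mapping: dict[str, float]) -> np.ndarray:
    v = np.zeros(N_DISEASES)
    for name, val in mapping.items():
        v[DISEASES.index(name)] = val
    return v


def elsi_like_truth(seed: int | None = None) -> GroundTruth:
    """Default ground truth emulating the ageing-cohort study conditions.

    Thresholds are centred by a mean-field correction,
    tau_i = logit(p_i) - sum_j w_ij p_j, minus the expected sex/age shift
    under the default stratum mix, so population-average marginals land near
    the target prevalences despite the couplings and stratum effects.
    """
    W = np.zeros((N_DISEASES, N_DISEASES))
    for a, b, w in _EDGES:
        i, j = DISEASES.index(a), DISEASES.index(b)
        W[i, j] = W[j, i] = w

    sex_shift = _vec({
        "hypertension": -0.32, "back_problems": -0.53, "depression": -0.55,
        "osteoporosis": -1.1, "arthritis_rheumatism": -0.5,
        "high_cholesterol": -0.25, "cataract": -0.2, "renal_failure": 0.3,
    })
    age_shift = _vec({
        "hypertension": 0.45, "cataract": 0.95, "heart_problems": 0.40,
        "diabetes": 0.30, "glaucoma": 0.50, "macular_degeneration": 0.80,
        "osteoporosis": 0.70, "arthritis_rheumatism": 0.30,
        "alzheimers": 1.30, "parkinsons": 0.85, "cancer": 0.30,
        "haemorrhagic_stroke": 0.35, "depression": -0.15, "asthma": -0.15,
    })
    # centre for the default mix: P(male)=0.4368, E[age band index]=0.7305
    tau = logit(_TARGET_PREV) - W @ _TARGET_PREV - 0.4368 * sex_shift - 0.7305 * age_shift

    outcome_coeffs = {
        HOSPITALISED: OutcomeModel(
            intercept=-2.85,
            disease_coefs=_vec({
                "heart_problems": 0.55, "cancer": 0.60, "haemorrhagic_stroke": 0.55,
                "renal_failure": 0.60, "depression": 0.30, "diabetes": 0.25,
                "copd": 0.30, "alzheimers": 0.40, "hypertension": 0.10,
            }),
            male=0.22, age_60_74=0.10, age_75=0.30,
        ),
        # mean number of admissions beyond the index stay (log link)
        READMISSIONS: OutcomeModel(
            intercept=-0.70,
            disease_coefs=_vec({"renal_failure": 0.25, "copd": 0.20, "heart_problems": 0.15}),
            male=0.05, age_60_74=0.0, age_75=-0.25,
        ),
        # mean days of the most recent stay (log link)
        LENGTH_OF_STAY: OutcomeModel(
            intercept=1.60,
            disease_coefs=_vec({"heart_problems": 0.15, "haemorrhagic_stroke": 0.25,
                                "cancer": 0.20, "renal_failure": 0.20}),
            male=0.50, age_60_74=0.05, age_75=0.25,
        ),
    }

    missing_model = {"intercept": -3.0, "male": 0.10, "age_60_74": 0.35, "age_75": 0.70}

    return GroundTruth(
        edge_weights=W,
        thresholds=tau,
        outcome_coeffs=outcome_coeffs,
        community_labels=dict(_COMMUNITIES),
        missing_model=missing_model,
        sex_shift=sex_shift,
        age_shift=age_shift,
        seed=seed,
    )


#: Sex x age-band mix matching the analysed complete-case sample
#: (56.3% female; bands 42.9% / 41.2% / 16.0%), treated as independent margins.
ELSI_STRATUM_MIX = {
    (sex, age): ps * pa
    for sex, ps in zip(SEXES, (0.5632, 0.4368))
    for age, pa in zip(AGE_GROUPS, (0.4290, 0.4115, 0.1595))
}


def generate_cohort(
    truth: GroundTruth,
    n: int,
    stratum_mix: dict[tuple[str, str], float] | None = None,
    seed: int = 0,
    include_index_admission: bool = True,
    apply_missing: bool = True,
    weight_sigma: float = 0.5,
) -> pd.DataFrame:
    """Draw a person-level cohort table from the ground truth.

    Diseases come from the Ising model with stratum-shifted thresholds
    (exact sampling when all couplings are zero, parallel-chain Gibbs
    otherwise); hospitalisation is Bernoulli on a logistic predictor;
    readmission counts are 1 + Poisson (the index admission is counted, so
    the total is >= 1 whenever hospitalised; set
    ``include_index_admission=False`` for the excess-admissions convention);
    length of stay is Gamma with log-link mean. Survey weights are lognormal
    with unit mean. Missingness is applied last via `apply_missingness`.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mix = ELSI_STRATUM_MIX if stratum_mix is None else stratum_mix
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    if np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError("stratum_mix proportions must be nonnegative and sum to 1")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    independent = not np.any(truth.edge_weights)

    frames = []
    for (sex, age), m in zip(keys, counts):
        if m == 0:
            continue
        age_idx = AGE_GROUPS.index(age)
        tau = truth.stratum_thresholds(sex, age_idx)
        if independent:
            X = (rng.random((m, N_DISEASES)) < expit(tau)).astype(float)
        else:
            X = sample_ising_gibbs(
                truth.edge_weights, tau, m, seed=rng.integers(2**31)
            )
        male = np.full(m, 1.0 if sex == "male" else 0.0)
        ages = np.full(m, age_idx)

        eta_h = truth.outcome_coeffs[HOSPITALISED].linear_predictor(X, male, ages)
        hosp = (rng.random(m) < expit(eta_h)).astype(float)

        eta_r = truth.outcome_coeffs[READMISSIONS].linear_predictor(X, male, ages)
        extra = rng.poisson(np.exp(eta_r))
        readm = (1 if include_index_admission else 0) + extra
        readm = np.where(hosp == 1, readm, 0).astype(float)

        eta_l = truth.outcome_coeffs[LENGTH_OF_STAY].linear_predictor(X, male, ages)
        shape = truth.los_shape
        los = rng.gamma(shape, np.exp(eta_l) / shape)
        los = np.where(hosp == 1, np.round(los, 2), 0.0)

        w = rng.lognormal(mean=-(weight_sigma**2) / 2, sigma=weight_sigma, size=m)

        df = pd.DataFrame(X, columns=list(DISEASES))
        df[HOSPITALISED] = hosp
        df[READMISSIONS] = readm
        df[LENGTH_OF_STAY] = los
        df[SEX] = sex
        df[AGE_GROUP] = age
        df[SURVEY_WEIGHT] = w
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)
    # deterministic shuffle so strata are interleaved as in a survey file
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    if apply_missing:
        table = apply_missingness(table, truth.missing_model, seed=rng.integers(2**31))
    return table


def apply_missingness(
    table: pd.DataFrame, missing_model: dict[str, float], seed: int = 0
) -> pd.DataFrame:
    """Blank out each person's disease/outcome block with MAR probability.

    The logit of being incomplete may depend only on sex and age group — the
    always-observed covariates — which is what makes the mechanism MAR and
    the IPW correction valid. A model referencing any maskable field is
    rejected.
    """
    bad = set(missing_model) - set(MISSING_MODEL_TERMS)
    if bad:
        raise ValueError(
            f"missing model may only reference always-observed covariates "
            f"{MISSING_MODEL_TERMS}, got {sorted(bad)}"
        )
    rng = np.random.default_rng(seed)
    male = (table[SEX] == "male").to_numpy(float)
    age_idx = table[AGE_GROUP].map({a: i for i, a in enumerate(AGE_GROUPS)}).to_numpy()
    eta = (
        missing_model.get("intercept", -np.inf)
        + missing_model.get("male", 0.0) * male
        + missing_model.get("age_60_74", 0.0) * (age_idx == 1)
        + missing_model.get("age_75", 0.0) * (age_idx == 2)
    )
    p_miss = expit(eta)
    mask = rng.random(len(table)) < p_miss
    out = table.copy()
    out.loc[mask, list(MASKABLE_COLUMNS)] = np.nan
    return out
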