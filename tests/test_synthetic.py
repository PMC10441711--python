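import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.special import expit, logit

from morbnet.catalog import (
    AGE_GROUP,
    DISEASES,
    HOSPITALISED,
    LENGTH_OF_STAY,
    N_DISEASES,
    READMISSIONS,
    SEX,
    SURVEY_WEIGHT,
)
from morbnet.synthetic import (
    ELSI_STRATUM_MIX,
    GroundTruth,
    InvalidModelError,
    OutcomeModel,
    apply_missingness,
    elsi_like_truth,
    enumerate_ising,
    generate_cohort,
    sample_ising_exact,
    sample_ising_gibbs,
)


def _null_outcomes(intercept=-2.0):
    return {
        k: OutcomeModel(intercept=intercept, disease_coefs=np.zeros(N_DISEASES))
        for k in (HOSPITALISED, READMISSIONS, LENGTH_OF_STAY)
    }


def _independent_truth(prev=0.2, **kw):
    truth = elsi_like_truth()
    return GroundTruth(
        edge_weights=np.zeros((N_DISEASES, N_DISEASES)),
        thresholds=np.full(N_DISEASES, logit(prev)),
        outcome_coeffs=kw.pop("outcome_coeffs", _null_outcomes()),
        community_labels=truth.community_labels,
        missing_model=kw.pop("missing_model", {"intercept": -np.inf}),
        **kw,
    )


class TestExactSampler:
    def test_two_independent_nodes_are_uniform_over_states(self):
        W = np.zeros((2, 2))
        states, probs = enumerate_ising(W, np.zeros(2))
        assert np.allclose(probs, 0.25)

    def test_pairwise_coupling_log2_gives_two_fifths_on_both_active(self):
        # unnormalised state weights 1,1,1,2 -> P(1,1) = 2/5
        W = np.array([[0.0, np.log(2)], [np.log(2), 0.0]])
        states, probs = enumerate_ising(W, np.zeros(2))
        p11 = probs[np.all(states == 1, axis=1)][0]
        assert np.isclose(p11, 0.4)
        X = sample_ising_exact(W, np.zeros(2), 200_000, seed=1)
        assert abs(np.mean(np.all(X == 1, axis=1)) - 0.4) < 0.005

    def test_three_fair_coins_under_null_couplings(self):
        states, probs = enumerate_ising(np.zeros((3, 3)), np.zeros(3))
        assert np.isclose(probs[np.all(states == 1, axis=1)][0], 1 / 8)

    def test_rejects_large_p_and_asymmetric_couplings(self):
        with pytest.raises(ValueError, match="(?i)gibbs"):
            sample_ising_exact(np.zeros((17, 17)), np.zeros(17), 10)
        W = np.zeros((3, 3))
        W[0, 1] = 0.5  # not symmetrised
        with pytest.raises(InvalidModelError):
            sample_ising_exact(W, np.zeros(3), 10)


class TestGibbsSampler:
    def test_independent_marginals_match_logistic_thresholds(self):
        tau = np.array([-1.0, 0.0, 0.7])
        X = sample_ising_gibbs(np.zeros((3, 3)), tau, 40_000, seed=2)
        se = np.sqrt(expit(tau) * (1 - expit(tau)) / len(X))
        assert np.all(np.abs(X.mean(0) - expit(tau)) < 4 * se)

    def test_matches_exact_enumeration_on_coupled_pair(self):
        W = np.array([[0.0, np.log(2)], [np.log(2), 0.0]])
        X = sample_ising_gibbs(W, np.zeros(2), 50_000, seed=3)
        assert abs(np.mean(np.all(X == 1, axis=1)) - 0.4) < 0.01

    def test_total_variation_against_enumeration_small_p(self):
        rng = np.random.default_rng(4)
        p = 6
        W = np.zeros((p, p))
        for i, j, w in [(0, 1, 0.9), (1, 2, 0.7), (3, 4, 1.1), (2, 3, 0.4), (4, 5, 0.8)]:
            W[i, j] = W[j, i] = w
        tau = np.linspace(-1.5, 0.5, p)
        states, probs = enumerate_ising(W, tau)
        X = sample_ising_gibbs(W, tau, 100_000, seed=5)
        code = (X @ (2.0 ** np.arange(p))).astype(int)
        emp = np.bincount(code, minlength=2**p) / len(X)
        exact = np.zeros(2**p)
        exact[(states @ (2.0 ** np.arange(p))).astype(int)] = probs
        tv = 0.5 * np.abs(emp - exact).sum()
        assert tv < 0.02

    def test_fixed_seed_reproduces_matrix(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        a = sample_ising_gibbs(W, np.zeros(4), 500, seed=9)
        b = sample_ising_gibbs(W, np.zeros(4), 500, seed=9)
        assert np.array_equal(a, b)

    def test_rejects_invalid_chain_settings(self):
        with pytest.raises(ValueError):
            sample_ising_gibbs(np.zeros((2, 2)), np.zeros(2), 10, thin=0)


class TestGenerateCohort:
    def test_null_effects_calibrate_hospitalisation_prevalence(self):
        truth = _independent_truth(outcome_coeffs=_null_outcomes(intercept=logit(0.12)))
        coh = generate_cohort(truth, 30_000, seed=6)
        prev = np.average(coh[HOSPITALISED], weights=coh[SURVEY_WEIGHT])
        assert abs(prev - 0.12) < 0.01

    def test_stratum_counts_match_mix_within_binomial_error(self):
        truth = elsi_like_truth()
        coh = generate_cohort(truth, 8807, seed=7, apply_missing=False)
        n_female = (coh[SEX] == "female").sum()
        expected = 8807 * sum(v for (s, _), v in ELSI_STRATUM_MIX.items() if s == "female")
        assert abs(n_female - expected) < 4 * np.sqrt(8807 * 0.56 * 0.44)
        # reference stratum sizes of the emulated survey: 4960 female / 3847 male
        assert abs(n_female - 4960) < 200

    def test_same_seed_gives_byte_identical_table(self, elsi_truth):
        a = generate_cohort(elsi_truth, 1500, seed=8)
        b = generate_cohort(elsi_truth, 1500, seed=8)
        assert a.to_csv(index=False) == b.to_csv(index=False)

    def test_outcome_support_constraints_hold(self, small_cohort):
        hosp = small_cohort[small_cohort[HOSPITALISED] == 1]
        assert (hosp[READMISSIONS] >= 1).all()
        assert (hosp[LENGTH_OF_STAY] >= 0).all()
        assert (small_cohort[SURVEY_WEIGHT] > 0).all()
        assert small_cohort[SEX].notna().all() and small_cohort[AGE_GROUP].notna().all()

    def test_excess_admission_convention_allows_counts_of_one_meaning_zero_extra(self):
        truth = _independent_truth()
        coh = generate_cohort(truth, 4000, seed=10, include_index_admission=False)
        hosp = coh[coh[HOSPITALISED] == 1]
        assert (hosp[READMISSIONS] >= 0).all()
        assert (hosp[READMISSIONS] == 0).any()

    def test_rejects_bad_inputs(self, elsi_truth):
        with pytest.raises(ValueError):
            generate_cohort(elsi_truth, 0, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(elsi_truth, 10, stratum_mix={("female", "50-59"): 0.5}, seed=0)

    def test_null_coupling_prevalences_match_thresholds(self):
        truth = _independent_truth(prev=0.3)
        coh = generate_cohort(truth, 50_000, seed=11)
        prev = np.average(
            coh[list(DISEASES)], weights=coh[SURVEY_WEIGHT], axis=0
        )
        se = np.sqrt(0.3 * 0.7 / len(coh)) * 1.6  # weighted-mean SE inflation bound
        assert np.all(np.abs(prev - 0.3) < 3 * se + 0.01)

    def test_doubling_disease_effect_raises_prevalence_among_diseased(self):
        base = np.zeros(N_DISEASES)
        base[0] = 0.5
        strong = base.copy()
        strong[0] = 1.0
        prevs = []
        for coefs in (base, strong):
            oc = _null_outcomes()
            oc[HOSPITALISED] = OutcomeModel(intercept=-2.0, disease_coefs=coefs)
            truth = _independent_truth(prev=0.3, outcome_coeffs=oc)
            coh = generate_cohort(truth, 30_000, seed=12)
            diseased = coh[coh[DISEASES[0]] == 1]
            prevs.append(diseased[HOSPITALISED].mean())
        assert prevs[1] > prevs[0]


class TestMissingness:
    def test_zero_probability_leaves_table_unchanged(self, small_cohort):
        out = apply_missingness(small_cohort, {"intercept": -np.inf}, seed=0)
        pd.testing.assert_frame_equal(out, small_cohort)

    def test_expected_incomplete_count_at_survey_rate(self):
        # masking 9412 rows at rate 0.064 should leave about 8807 complete
        truth = _independent_truth()
        coh = generate_cohort(truth, 9412, seed=13)
        masked = apply_missingness(coh, {"intercept": float(logit(0.064))}, seed=14)
        incomplete = masked[list(DISEASES)].isna().any(axis=1).sum()
        sd = np.sqrt(9412 * 0.064 * (1 - 0.064))
        assert abs(incomplete - 605) < 4 * sd

    def test_age_effect_raises_missingness_in_oldest_band(self, small_cohort):
        masked = apply_missingness(
            small_cohort, {"intercept": -2.5, "age_75": 1.5}, seed=15
        )
        miss = masked[DISEASES[0]].isna()
        old = masked[AGE_GROUP] == "75+"
        assert miss[old].mean() > miss[~old].mean()

    def test_rejects_model_on_maskable_fields(self, small_cohort):
        with pytest.raises(ValueError, match="always-observed"):
            apply_missingness(small_cohort, {"intercept": -2.0, "diabetes": 1.0}, seed=0)


@given(st.integers(0, 2**31 - 1))
def test_ground_truth_thresholds_shift_monotonically_with_age(seed):
    truth = elsi_like_truth(seed=seed)
    t0 = truth.stratum_thresholds("female", 0)
    t2 = truth.stratum_thresholds("female", 2)
    rising = truth.age_shift > 0
    assert np.all(t2[rising] > t0[rising])
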