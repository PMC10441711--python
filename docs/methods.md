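# Methods

`morbnet` implements a two-arm analysis of how multimorbidity relates to
hospitalisation in adults aged 50+: survey-weighted outcome regressions under
two multimorbidity definitions, and conditional-dependence ("Ising") network
analysis of 19 chronic conditions plus hospitalisation, stratified by sex and
age band, with bootstrap stability diagnostics. Because the survey microdata
this kind of analysis is run on are access-restricted, the package ships a
synthetic-cohort generator with known ground truth; every stage is exercised
and validated against that ground truth.

## The data model

A cohort is a person-level table with 19 binary condition indicators
(physician-diagnosis self-reports: hypertension, back problems, high
cholesterol, cataract, arthritis/rheumatism, depression, diabetes,
osteoporosis, heart problems, glaucoma, COPD, haemorrhagic stroke, cancer,
asthma, renal failure, diabetic retinopathy, macular degeneration,
Parkinson's, Alzheimer's — this order is canonical and defines node indexing
everywhere), three outcomes (hospitalised in the last 12 months, yes/no;
number of admissions in those 12 months; days of the most recent stay), sex,
age band (50–59 / 60–74 / 75+), and a positive survey weight. Disease and
outcome fields may be missing as a block; sex, age and weight never are.

Multimorbidity is a simple count over the 19 conditions: MM2 means at least
two, MM3 at least three; MM3 cases are a subset of MM2 cases.

## Synthetic cohorts

Conditions are drawn from a pairwise Ising model on {0,1} variables,

    P(x) ∝ exp( Σ_i τ_i x_i + Σ_{i<j} w_ij x_i x_j ),

whose conditionals are logistic — the same parameterisation the estimator
assumes, so planted couplings are directly comparable to estimates. The
{0,1} domain (rather than ±1) is used everywhere in the package.

Two samplers are provided. For p ≤ 16 nodes, exact sampling by enumeration
of all 2^p states. For the full 19-condition model, Gibbs sampling with
single-site logistic conditionals; the implementation runs up to 512
independent chains in parallel (vectorised across chains), discards
`burn_in` = 1000 full sweeps and records states every `thin` = 10 sweeps.
Parallel chains make draws closer to independent than one long thinned chain
at the same cost; agreement with exact enumeration is tested in total
variation (TV < 0.02 at p = 6 with 10^5 draws).

The default scenario plants: five comorbidity communities
(cardiovascular–cancer–eye; musculoskeletal–depression–renal; diabetes and
complications; respiratory; neurodegenerative) connected by within-community
couplings of 0.3–1.5 log-odds units and a few weaker bridges; marginal
prevalences typical of a 50+ household survey (hypertension ≈ 52%,
Parkinson's ≈ 1%), with sex and age shifts on the log-odds scale sized so
that, e.g., hypertension lands near 56% in women vs 48% in men and rises
from ~42% to ~66% across age bands. Thresholds are centred by a mean-field
correction τ_i = logit(p_i) − Σ_j w_ij p_j minus the expected sex/age shift
under the default stratum mix (56.3% female; age bands 42.9/41.2/16.0%),
which keeps population marginals near their targets despite couplings —
exact calibration is only guaranteed (and only asserted) when couplings are
null.

Outcomes follow generalised-linear predictors on the disease indicators plus
sex/age terms: hospitalisation is Bernoulli with a logistic link
(intercept −2.85, yielding ≈ 10% prevalence); the admission count is
1 + Poisson(exp(η)) — the index admission is counted, so the total is ≥ 1
whenever hospitalised; a flag switches to the excess-admissions convention —
and length of stay is Gamma with log-link mean and shape 1.5 (any positive
right-skewed family would do; Gamma composes naturally with the log link).
Survey weights are lognormal with unit mean (σ = 0.5). Missingness blanks a
person's whole disease/outcome block with probability
logistic(α + β·covariates) where the covariates may only be sex and age
group — exactly the missing-at-random structure the IPW correction assumes;
a model referencing a maskable field is rejected. The default α = −3.0 with
age effects +0.35/+0.70 gives ≈ 6% incompleteness, so a draw of 9,412 leaves
roughly 8,800 complete cases, matching the emulated survey's scale.

What the generator does *not* emulate: multistage cluster sampling (weights
are iid lognormal, not design-based), informative missingness beyond
sex/age, reporting error in self-reports, and any time structure. Passing
tests therefore demonstrate method correctness under the assumed model, not
robustness to those real-data features.

## Preprocessing and weights

Complete cases are rows with no missing value among the 19 conditions and
hospitalisation. The completeness model is logistic regression of the
complete-case indicator on sex + age group, fitted on all rows; each
complete case gets combined weight survey_weight / P(complete), rescaled to
unit mean (estimates are invariant to the rescaling; it keeps effective
sample sizes honest in variance formulas). Sex and age group are the minimal
MAR-consistent covariate set — the fields that are never missing; the choice
is a package default, not a claim about any particular study's model. A
sex×age stratum with no complete rows aborts the fit with the stratum named,
since its weight would diverge.

## Outcome regressions

Hospitalisation is binary, but effects are reported as prevalence ratios,
not odds ratios, so the model is log-link Poisson pseudo-likelihood with the
combined weight. Because Poisson variance misspecifies a Bernoulli outcome,
all inference uses the weighted sandwich covariance B⁻¹MB⁻¹ with
B = Σ w μ xxᵀ and M = Σ w²(y−μ)² xxᵀ, computed directly from the fitted
coefficients (point estimates come from a standard IRLS GLM fit). On a
saturated two-group design the PR equals the ratio of weighted prevalences
exactly — an identity the tests assert to 1e-9 — and under a null the robust
95% CI covers PR = 1 at nominal rate (±2% at 1,000 replicates, n = 1,000).

Readmission count and length of stay are analysed among hospitalised persons
only, by weighted least squares with HC1 heteroscedasticity-robust standard
errors (classical SEs selectable). Readmissions are modelled linearly by
default — the convention of the table this mirrors — with a weighted Poisson
count alternative behind `readmission_family="poisson"`. All intervals use
the 1.96 normal quantile; no degrees-of-freedom correction is applied.

The suite fits, per MM subset (MM2, MM3) and outcome: (a) sex + age group
jointly, (b) age group within women, (c) age group within men. Reference
levels (female, 50–59) are emitted explicitly with PR = 1 / β = 0.

## Network estimation (eLASSO)

Each node (19 conditions + hospitalisation) is regressed on all others by
L1-penalised logistic regression along a descending grid of 100 log-spaced
penalties from λ_max (the smallest penalty that zeroes every coefficient,
computed from the data) down to 0.01·λ_max. The solver is glmnet-style
coordinate descent (IRLS outer loop, Gram-matrix active-set inner loop, warm
starts), compiled with numba, and satisfies the lasso KKT conditions at
tolerance 1e-6; tests cross-check whole solutions against an independent
solver (scikit-learn's saga) to ~1e-7. Duplicate binary rows are collapsed
into case weights before solving, which changes nothing statistically and
makes bootstrap re-estimation cheap.

Model selection per node minimises the extended BIC,

    EBIC_γ = −2ℓ + k·ln n + 2γ·k·ln(p−1),   γ = 0.25 by default,

where k is the neighbourhood size. The lasso path proposes the candidate
supports, but ℓ is the *unpenalised maximum likelihood* of each distinct
support (a "relaxed" refit), not the shrunken path likelihood: shrinkage
inflates −2ℓ by an amount that varies with λ and distorts the comparison
between supports, and with the refit the selection provably targets the same
criterion as an exhaustive all-subsets search — which the tests run on
4-node problems, requiring ≥ 95% exact agreement (observed: 100%). The
selected model's coefficients are also the ML refit, so edge weights are not
biased toward zero.

Edges are symmetrised with the AND rule by default (an edge exists only if
both directed coefficients are nonzero; OR selectable), with weight the mean
of the two directed coefficients (an absent direction contributes 0 under
OR). Binary predictors are left in 0/1 coding so weights are log-odds
interactions. Nodes constant within a stratum are dropped and recorded;
strata below 200 rows are skipped with a warning. Planted-graph recovery at
p = 10, n = 2,000 runs at sensitivity ≈ 1.0 and specificity ≈ 0.99 over 20
replicates, with all detected planted edges carrying the planted sign.

## Communities

Walktrap (walk length t = 4, the algorithm's convention; configurable) runs
on |w| affinities — couplings can be negative and random-walk transition
probabilities cannot, so the sign information is *not* used for community
structure; this is a limitation worth remembering when negative edges are
scientifically meaningful. The merge tree is cut at maximum weighted
modularity (igraph's implementation); isolated nodes become singletons; an
edgeless network yields all singletons with Q = 0. On the two-triangle
fixture the cut equals the exhaustive global modularity optimum
(Q = 5/14 ≈ 0.357, matched to 1e-9).

Community stability re-estimates the network and partition on `n_boot`
(default 100) row resamples, aligns each bootstrap partition to the original
by maximum-overlap Hungarian matching, and reports per-node agreement with
the consensus. "Consensus" is the modal aligned label; taking a median of
nominal labels is not meaningful as such, so the median over aligned integer
labels is reported alongside for completeness, and ties in the mode are
broken by a seeded uniform choice. Sorted eigenvalues of each bootstrap
network's modularity matrix are recorded as an additional spectrum-level
diagnostic; no pass/fail rule is attached to them. The overall stability
flag requires mean agreement ≥ 0.8, a non-singleton consensus community, and
median bootstrap modularity ≥ 0.05 — the last clause is what flags
structureless (noise) data as unstable even though its trivial all-singleton
partition replicates perfectly.

## Node metrics

Predictability (CC) is the in-sample correct-classification rate of each
node from the logistic conditional implied by its estimated neighbourhood,
thresholded at 0.5, reported against the best constant classifier
max(p̂, 1−p̂). In-sample CC is the convention of the predictability
literature this follows; a cross-validated variant is a flag away.

Centralities use |w|: strength Σ_j |w_ij|; shortest-path measures on edge
lengths 1/|w_ij|; closeness (n_reachable − 1)/Σd so isolated nodes and
disconnected strata (plausible when rare diseases drop out) give 0 rather
than infinities; betweenness is the unnormalised weighted Brandes count;
participation P_i = 1 − Σ_s (κ_is/κ_i)² over the Walktrap communities. All
four are checked against brute-force enumeration on ≤ 8-node fixtures.

## Stability suite

Nonparametric bootstrap (default B = 500; smaller budgets for interactive
runs) re-estimates the full network on row resamples and reports per-edge
95% quantile intervals. The edge difference test declares two edge
magnitudes different when the bootstrap interval of their difference
excludes zero; under equal planted weights its empirical size is 5% ± 3%
(checked at 200 outer replicates with B = 200).

Case-dropping bootstrap draws B subsamples *without* replacement at each
retention proportion (grid 0.9…0.3 step 0.1, plus 0.25; B per proportion,
with the total-budget interpretation available by passing a smaller B),
recomputes centralities, and takes the Spearman correlation with the
original values — Spearman because the CS-coefficient is about preserving
the *ordering* of nodes. CS is the largest drop proportion at which the
correlation stays ≥ 0.7 in ≥ 95% of subsamples, requiring all smaller drops
to qualify too (monotone reading); it is capped at the grid maximum 0.75
(reported as ≥ 0.75) and reported as < min when even the smallest drop
fails. Replicate estimation failures are tolerated up to 10% and excluded;
degenerate resamples do occur in small strata.

## Pipeline and determinism

`RunConfig` + `run()` execute cohort → IPW → regressions → stratified
networks → communities (+ bootstrap) → node metrics → stability, writing
CSV/JSON/GraphML artifacts, a Markdown report and a manifest with a SHA-256
hash over all content (timing and filesystem paths excluded). All
randomness derives from the single config seed through one generator, so a
rerun of the same config is byte-identical; the test suite asserts manifest-
hash equality at full survey scale (9,412 drawn rows, 5 strata).

## Problem sizes and budgets

Defaults are publication-scale (B = 500 edge bootstraps, 100 community
bootstraps, 500 case-dropping resamples per proportion). The bundled
scenario configuration, the examples and the test suite use reduced budgets
(λ grids of 20–50 points, bootstrap budgets of 6–200, simulation replicates
of 10–1,000 chosen per check) — sized so the full validation battery runs on
one CPU in minutes while keeping every Monte-Carlo margin it asserts
(binomial error at the stated replicate counts). The methods themselves are
identical at every budget.

## Known limitations

- Community detection ignores coupling signs (|w| affinities).
- The completeness model is fixed to sex + age group; richer MAR mechanisms
  need a custom model.
- CC is in-sample by default and optimistic to the usual degree.
- The generator's weights are iid, not design-based; sandwich variances are
  robust to weighting but not to cluster correlation, which the package does
  not model.
- The CS grid caps at 0.75; stability beyond that is not measurable by
  construction.
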