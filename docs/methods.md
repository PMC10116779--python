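# Methods

This note documents the models, conventions and numerical choices behind
`bmineq`, in the spirit of a statistical package's model documentation.

## Outcome definitions

BMI categories use half-open intervals `[lower, upper)`: underweight
(< 18.5), healthy [18.5, 25), overweight [25, 30), obesity I [30, 35),
II [35, 40), III (≥ 40). The three nested binary outcomes are excess weight
(BMI ≥ 25), obesity (≥ 30) and morbid obesity (≥ 35). The half-open
convention resolves the boundary ambiguity of the usual "≥" category
notation; a BMI of exactly 30 is obese, 29.999 is not. Underweight records
keep all flags at 0 and stay in denominators. Responder rows with BMI below
the 12 kg/m² floor are treated as implausible and excluded during
validation, with a logged count.

## Rank and sign conventions

All three deprivation dimensions are integer-coded in increasing deprivation
order (IMD quintile 5, NS-SEC class 6, education level 8 = most deprived).
Weighted fractional ranks place the **most deprived at the low end** of the
(0, 1) rank scale: a record's rank is the cumulative weight share of strictly
more deprived categories plus half its own category's share, so ties within
a category always share the mid-rank (no jittering) and the weighted mean
rank is exactly 0.5. Under this convention a *negative* concentration index
means the outcome is concentrated among the most deprived — the reading used
for every reported value. Reversing the order flips the sign exactly
(mirror-symmetry property, tested).

## Concentration indices

Erreygers' corrected index is computed as `8·cov_w(y, r)/(b − a)`, the
simplified form of `(4µ/(b−a))·(2·cov/µ)`, so it remains defined when µ = 0.
The Wagstaff bounded-outcome normalisation is
`2·cov_w(y, r)·(b − a)/((b − µ)(µ − a))`, undefined when the mean sits at a
bound. Binary outcomes use bounds (0, 1); continuous BMI uses configurable
bounds, default (12, 60), chosen to cover the plausible adult range — results
for BMI-level indices scale with this choice and it is surfaced as an
explicit parameter. For 0/1 outcomes the identity `E = 4µ(1−µ)·W` holds to
machine precision and is enforced in tests.

Inference default is a seeded nonparametric bootstrap (1,000 replicates in
the library default; pipeline configs may lower it): records are resampled
with their weights, ranks are recomputed per replicate, the SE is the
replicate SD and p the two-sided normal approximation. The alternative
delta method uses the convenient-regression representation — the weighted
least-squares slope of `(8·var_w(r)/(b−a))·y` on `r` equals the Erreygers
index — with an HC1 robust slope SE (the Wagstaff version holds µ fixed in
the normaliser, an approximation). The two agree within ~15% at n = 5,000
on survey-like data (tested). Null calibration: on zero-gradient synthetic
surveys the 5%-level rejection rate is ≈ 0.05 (measured in the acceptance
run). Inference requires n ≥ 30; strata below a configurable floor
(default 100) are skipped and reported, not silently dropped.

## Survey weighting

Response propensity is a main-effects logistic model (statsmodels GLM) of
the responded indicator on fully observed covariates; IPW factors are
1/propensity for responders, 0 for non-responders, with the propensity
floored at 0.02 to bound variance inflation. Raking is plain iterative
proportional fitting on margin proportions, convergence tolerance 1e-6 on
every margin, maximum 50 sweeps; one-dimensional targets therefore reduce
to exact post-stratification in a single sweep, and each sweep preserves the
total weight exactly. Combined weights are capped at 5× the responder median
(cap events counted) and mean-normalised over responders. The floor and cap
have no external reference values; both are configurable and their defaults
are deliberately mild.

## Dissimilarity index and Shapley decomposition

Explained inequality is the classical dissimilarity index over fitted
probabilities, `DI = Σ w|p − p̄|/(2 p̄ Σ w)`; published contribution shares
depend on this formula choice, so it is stated prominently. The outcome
model is a weighted logistic regression with categorical main effects — the
standard choice in the inequality-of-opportunity literature the DI comes
from. Fits use a ridge-damped Newton solver (ridge 1e-8 on non-intercept
terms, step-halving, escalating penalty under near-separation with a
warning); it matches statsmodels GLM fitted probabilities to ≤ 1e-6 (tested)
and exists because a decomposition needs 2^m subset fits, and again per
bootstrap replicate.

Shapley values are computed by exact subset enumeration with memoised fits,
weights `|S|!(m−|S|−1)!/m!`; DI(∅) is defined as 0 so the efficiency
identity `Σ shapley = DI(full)` holds exactly (checked to 1e-8 on every
run). Enumeration equals the brute-force average over all m! elimination
orders (tested at m = 4 and m = 5). Factor p-values bootstrap the whole
decomposition over resampled records (default 200 replicates; two-sided
normal approximation); non-finite replicates are dropped with a log entry
and more than 5% drops is an error. The specification ladder mirrors the
stepwise design used in excess-weight inequality studies: specification 1 =
region, age group, gender, ethnicity + the deprivation dimension under
study; 2 adds limiting illness, marital status and urbanicity; 3 adds the
remaining deprivation dimensions. Specifications are compared by
BIC = k·ln(n) − 2·loglik.

## Synthetic-data generator

The generator emulates an HSE-2019-like adult sample: 9 regions (sampling
shares from the survey's regional observation counts), 7 age bands, 2
genders, 5 ethnic groups, 8 education levels, 6 occupation classes, 5 IMD
quintiles, limiting-illness (25%), 5 marital states, 82% urban. BMI follows
an additive linear model over covariate levels with Gaussian residual
(default SD 5.0 kg/m²) floored at 12 kg/m²; the default intercept and
gradients (e.g. +0.35 kg/m² per IMD quintile, +1.6 for limiting illness, a
hump-shaped age profile) are fixed a priori to reproduce a mean BMI ≈ 27.9
and excess-weight prevalence ≈ 0.7. Binary flags are derived from
continuous BMI so spectrum analyses stay internally consistent; an optional
logistic mode simulates the excess-weight flag directly for calibration
studies with closed-form truth.

Dependence between IMD, education and occupation uses an equicorrelated
Gaussian copula (default ρ = 0.3) — a stand-in for the unknown real joint
distribution, chosen because the decomposition is only meaningful when
deprivation dimensions correlate. The one-factor representation
(z_d = √ρ·f + √(1−ρ)·e_d) is used both for sampling and for the exact
ground-truth computation: the triple's joint pmf is obtained by
Gauss–Hermite quadrature (80 nodes) over the shared factor, and all
population quantities — mean BMI (with an exact floor correction),
prevalences, and per-dimension concentration indices — are expectations
over the full discrete covariate grid, with no simulation.

Missingness is a logit on observed covariates only (never BMI itself), i.e.
missing-at-random by construction; the HSE-like preset puts weight on
limiting illness and age and calibrates the intercept by root-finding so the
population missing fraction is exactly 18.6%. Quota distortion multiplies
per-level sampling probabilities (preset: oversampled older and female
respondents) to create the margin imbalance that raking corrects; ground
truth always describes the undistorted population.

What the generator does **not** emulate: the real multistage PSU/postcode
design (so design-based variance is optimistic relative to a clustered
survey), spatial autocorrelation, informative design weights, and the true
HSE covariate joint distribution. Passing tests therefore demonstrate the
estimators' correctness under known data-generating processes, not the
fidelity of any particular published estimate.

## Problem sizes and reproducibility

Defaults used in the shipped analyses: survey size N = 6,387; bootstrap
500–1,000 replicates for index inference; 100–200 replicates for MAR-bias
studies; 400–500 null simulations for calibration checks; parameter recovery
at n = 200,000. Every stochastic step draws an independent child seed from
one master seed (`numpy` SeedSequence), so the same config + seed reproduces
a byte-identical report payload.

## Known limitations

- Regional analyses use within-stratum fractional ranks by default; a flag
  switches to nationally computed ranks (with delta-method SEs, since the
  bootstrap re-ranks within the resample).
- The Wagstaff delta-method SE treats µ as fixed; use the bootstrap when its
  precision matters.
- Shapley p-values at the full 10-factor specification are expensive
  (replicates × 2^10 fits); ladders default to point estimates with p-values
  opt-in.
- The dissimilarity-index and outcome-model choices are declared package
  conventions; other DI variants or model families would shift contribution
  percentages.
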