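# bmineq

Accounting for socio-economic inequality in excess weight from individual-level
survey data: survey weighting, concentration indices, and Shapley decomposition
of explained inequality.

The package is aimed at health-economics and public-health analysts working
with surveys such as the Health Survey for England (HSE): one row per adult
with a measured BMI, socio-demographic covariates, and deprivation indicators
(IMD quintile, NS-SEC occupational class, NVQ-based education level). It
implements the full analytic chain such studies need, plus a synthetic-data
generator with exact analytic ground truth so every estimator can be
validated without access to the restricted microdata.

## What it computes

**Weighting.** BMI is typically missing for a sizeable share of respondents
(~18.6% in HSE 2019). Responders are reweighted by inverse probability
weighting (IPW) — the inverse of a logistic response propensity fitted on
observed covariates, valid under missing-at-random — and the weighted sample
is raked (iterative proportional fitting) to known population margins. The
combined analysis weight is `design × IPW × raking`, capped and
mean-normalised.

**Concentration indices.** With weighted fractional rank *r* over a
deprivation-ordered dimension (most deprived at the low end of the rank
scale), weighted mean µ, and outcome bounds (a, b):

- Erreygers corrected concentration index (CCI):
  `E = (4µ/(b−a)) · (2·cov_w(y, r)/µ) = 8·cov_w(y, r)/(b−a)`, range [−1, 1];
  negative values mean the outcome is concentrated among the most deprived.
- Wagstaff index: `W = 2·cov_w(y, r)·(b−a)/((b−µ)(µ−a))`; for a binary
  outcome the two are linked by `E = 4µ(1−µ)·W`.

Standard errors come from a seeded nonparametric bootstrap (ranks recomputed
per replicate) or a convenient-regression delta method.

**Decomposition.** Explained inequality of a binary outcome is the
dissimilarity index of fitted probabilities from a weighted logistic model,
`DI = Σ w_i |p_i − p̄| / (2 p̄ Σ w_i)`. Each factor's independent contribution
is its Shapley value — the average marginal DI contribution over all factor
elimination orders, computed by exact subset enumeration — with a nested
three-specification ladder (intrinsic characteristics → personal
circumstances → all deprivation dimensions) compared by BIC.

## Worked example

```python
import bmineq as bq

cfg = bq.AnalysisConfig(
    synthetic=bq.SyntheticConfig.hse_default(n_individuals=6387, seed=2019),
    outcomes=("excess_weight", "obese"),
    strata=("national",),
    bootstrap_reps=500,
    decomposition_outcomes=("excess_weight",),
    seed=7,
)
report = bq.run_analysis(cfg)
print(report.indices[["dimension", "outcome", "variant",
                      "index_value", "se", "p_value"]].round(4))
```

produces (seeded, reproducible):

```
   dimension       outcome   variant  index_value     se  p_value
imd_quintile excess_weight erreygers      -0.0853 0.0140      0.0
imd_quintile excess_weight  wagstaff      -0.1048 0.0188      0.0
imd_quintile         obese erreygers      -0.1084 0.0155      0.0
  occupation excess_weight erreygers      -0.1126 0.0142      0.0
   education excess_weight erreygers      -0.1146 0.0144      0.0
...
```

Every index is negative: in this synthetic population (whose BMI model has
monotone deprivation gradients) excess weight and obesity are concentrated
among the more deprived, and the bootstrap p-values reject no concentration.
The decomposition block of the same report gives, for specification 2,
`DI = 0.0522` with limiting illness the largest contributor (24.1%),
followed by region (23.6%) and IMD (18.4%); `bq.compare_variants(report)`
confirms Erreygers/Wagstaff sign agreement 1.0 and rank correlation 1.0.

A `bmineq` console script exposes the same pipeline from the shell
(`simulate`, `weights`, `indices`, `decompose`, `run`, `compare`); see
`bmineq --help`.

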