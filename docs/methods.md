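# Methods

## Measurement model

A patient's repeated HbA1c results are modelled as

    y_ij = mu + b_i + e_ij,    b_i ~ N(0, sigma_b^2),    e_ij ~ N(0, sigma_w^2),

an intercept-only random-intercept (one-way random effects) model on the raw
mmol/mol scale. The target of estimation is the total within-individual
coefficient of variation CV_T = sigma_w / mu, a decimal fraction. "Total"
means pre-analytical, analytical and biological variation combined: routine
clinical data cannot separate them, and no attempt is made to.

The denominator of CV_T is the grand mean of all included records (not the
mean of per-patient means). This matches the intercept of an
observation-level fit; with unequal visit counts the two differ slightly,
and the observation-weighted mean is the one the model estimates.

## Estimators

**Moments (oracle).** The unbalanced one-way ANOVA estimator:
sigma_w^2 = SSW / (N - k) (pooled within-patient variance over k patients
and N records), and sigma_b^2 from equating the between-groups mean square
to its expectation, truncated at zero. This estimator is closed-form and
serves as the brute-force cross-check for REML.

**REML.** For this model the restricted likelihood profiles down to one
dimension in the variance ratio lambda = sigma_b^2 / sigma_w^2: given
lambda, the GLS intercept and the REML sigma_w^2 have closed forms. The
implementation minimises the profiled criterion over log(lambda) on
[-34, 34] (bounded scalar search, default xatol 1e-10, max 200 evaluations),
then polishes the interior optimum by root-solving the analytic profiled
score — value-based search alone is limited to ~1e-8 precision by
floating-point noise near the flat minimum. The boundary candidate
sigma_b^2 = 0 (whose profiled sigma_w^2 is SST / (N - 1)) is always
evaluated and wins if its criterion is lower, so estimates are constrained
non-negative. Inputs are standardised by the grand mean before optimisation,
which conditions the search and makes the fitted CV invariant under
rescaling of the data to ~1e-9 or better; the closed-form estimators are
invariant to ~1e-12 (i.e. floating-point rounding). On balanced designs with
interior solutions REML reproduces the moment estimator to better than 1e-6
relative, and it matches an independent general mixed-model implementation
(statsmodels MixedLM) on unbalanced data in the test suite.

Degenerate inputs: a patient with fewer than two records is a hard error; a
single-patient cohort returns that patient's sample SD with sigma_b = 0;
SSW = 0 (no within-patient variation anywhere) returns sigma_w = 0 without
optimisation.

**Confidence interval.** The default interval treats the grand mean as fixed
and pivots on sigma_w^2 ~ sigma_w^2 * chi2_{N-k} / (N - k), i.e.
[sw * sqrt(df / chi2_{1-a/2, df}), sw * sqrt(df / chi2_{a/2, df})] / mu with
df = N - k. Under the model this pivot is exact for the pooled-variance
estimator; dividing by the estimated mean adds O(cv / sqrt(N)) relative
noise, negligible at the sample sizes involved. A patient-level bootstrap
(percentile, default 500 resamples) is available behind a flag for designs
where the within-variance is heterogeneous.

**Sensitivity variants.** The crude arithmetic CV averages per-patient
s_i / ybar_i with equal patient weights; because low-mean patients have
small absolute SDs and all patients count equally, it typically sits below
the model CV on heterogeneous cohorts. The log-scale CV fits the components
on ln(y) and reports sqrt(exp(sigma_w,log^2) - 1), which approaches
sigma_w,log for small CVs.

## Cleaning cascade

Fixed stage order: unit filter → plausibility range → same-day dedup →
identical-run exclusion → minimum-count exclusion; BMI recoding applies to
the covariate table. The order is chosen so patient-level exclusions only
ever see plausible, deduplicated records. Details that matter:

- Range cuts are strict inequalities: 20.1 and 195.1 mmol/mol themselves
  survive. Sub-20.1 values are overwhelmingly percent results mis-recorded
  under mmol/mol units (they cluster near 7.7); they are excluded, never
  converted, because a recorded unit cannot be trusted enough to invert.
- "First result of the day" is first in file order; source extracts carry no
  intra-day timestamps.
- The identical-run rule compares values after rounding to 0.1 mmol/mol
  (typical reporting resolution) and removes a patient when any single value
  recurs on ≥ 4 distinct dates.
- BMI outside (14, 70) becomes missing, strict on both sides.
- The report counts removals per rule at record and patient level; a patient
  is attributed to the stage at which their last record vanished, and the
  identities records_in = records_out + Σ removals (and likewise for
  patients) are asserted on every run. The cascade is idempotent.

## Synthetic cohort generator

The generator emulates a primary-care HbA1c extract:

- **Strata.** Four diabetic-status strata with the study population's
  marginals: weights 0.254 / 0.126 / 0.057 / 0.563, true-mean centers 38.24
  / 48.74 / 70.17 / 58.70 mmol/mol and within-patient CVs 0.091 / 0.180 /
  0.157 / 0.194 for no-DM / prediabetes / T1DM / T2DM. Between-patient SDs
  are not published anywhere and are package choices: 3.5 / 4.0 / 14.0 /
  12.0 mmol/mol — tight for non-diabetics (a narrow normal range), wide for
  treated diabetes where targets, adherence and disease stage spread the
  population. True means are normal, truncated to (20.1, 195.1).
- **Within-patient noise.** Normal with SD = CV × true mean (constant CV on
  the raw scale), truncated at > 0 by resampling; reported values are then
  rounded to 0.1 mmol/mol.
- **Visit counts.** Discretised log-normal matched to median 11, IQR 7–18
  (sigma = ln(18/7) / (2 × 0.6745)); only these quantiles are known, and a
  log-normal is the natural single-parameter-family fit to a long-tailed
  count.
- **Dates.** First visit uniform over 2010–2019; subsequent gaps i.i.d.
  uniform on 30–365 days (≈ 11 visits × 197-day mean gap ≈ 5–6 years of
  follow-up, matching the typical first-to-last span). Later visits may run
  past the nominal end date; calendar-year subgroup analyses default to
  2010–2019 regardless.
- **Defects.** Percent-unit errors replace a value with N(7.7, 1.2) clipped
  to (3, 15), still tagged mmol/mol; implausible values are uniform on
  (195.2, 500); same-day duplicates are exact copies ordered directly after
  their source row; identical-run patients get ≥ 4 visits all carrying one
  value. Error bookkeeping (row indices, patient ids) is returned as a truth
  record so tests can verify the cleaning rules remove exactly what was
  injected.

What the generator does **not** emulate: disease progression or
medication-driven drift (each patient's true mean is constant), seasonality,
informative visit timing (sicker patients being tested more often — the
confounding-by-indication problem), status changes over time, and
correlation between covariates and HbA1c beyond the stratum structure.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the stated model, not robustness to those real-data features.

## Repeat-test transition matrices

One (first, second) pair per patient from the two chronologically earliest
records. Display bins are 5 mmol/mol wide anchored at the 48 mmol/mol
diagnostic cut-point (…, 43, 48, 53, 58, …), fully configurable; a 5-wide
grid cannot also contain 42, so the prediabetes lower bound is not an edge
by default. MCID exceedance probabilities (default 5.5 mmol/mol, with 5.0
available by configuration since both conventions circulate) are computed
from raw values per first-result bin — binning is presentation only.

The analytic companion computes the same matrix in closed form for two
conditionally independent N(mu, cv·mu) draws mixed over a discrete law of
true means (cell probabilities from normal CDF differences; MCID exceedance
by 64-node Gauss–Legendre quadrature per bin). Convergence of the empirical
builder to this matrix is asserted on synthetic cohorts; the sup-norm
comparison is restricted to first-result rows holding at least 5000 pairs at
the 50,000-patient size, chosen a priori so that binomial sampling noise
(SE ≤ ~0.007 per cell) sits an order of magnitude below the 0.02 tolerance.

## Clinical inference

`prob_beyond_mcid` evaluates 2(1 − Φ(MCID / (cv·mu))); with mu = 58, cv =
0.182, MCID = 5.5 this is 0.602. `misclassification_prob` gives the
probability a single result crosses a diagnostic threshold given a true
mean on one side of it. The CI-width planning simulation draws balanced
cohorts around a single common mean (the criterion concerns the
within-patient estimator, not between-patient structure; default mean 52.31
mmol/mol), estimates CV and its chi-square interval per replicate, and
reports widths in absolute percentage points of CV — "total width below 10
points" is read as a ±5-point half-width around a CV of 20%. At the 100 ×
4 design the median width is ≈ 3.2 points and interval coverage is ≈ 95%.

## Subgroups

Stratified estimates repeat the whole-cohort fit on each stratum's patients
(each patient's full record). Groups under 100 patients are suppressed:
counts are reported, estimates are not. Cross-classification over up to
four variables uses complete cases only. When a record-level diabetic-status
column exists, a patient contributes to a status stratum only a run of ≥ 4
consecutive results under that status; patients with no qualifying run are
excluded from the status analysis. Age bands are decades (≤10, 11–20, …,
>100); BMI bands are <18.5, 18.5–<25, 25–<30, 30–<35, >35, missing.

## Problem sizes in the test suite

Recovery tests use 2000 patients × 10 visits (CV Monte-Carlo SE ≈ 0.001,
an order of magnitude inside the ±0.01 tolerance); the coverage and CI-width
simulations use 500 replicates of the 100 × 4 design; transition-matrix
convergence uses 50,000 patients × 2 visits. These sizes put sampling noise
well inside every asserted tolerance while keeping the full suite under
half a minute.

## Known limitations

- CV_T pools all variation sources; no decomposition into analytical and
  biological components is offered.
- The chi-square interval is exact only under homogeneous within-patient
  variance; with strongly heterogeneous strata, use the bootstrap.
- With between-patient spread in true means, the pooled within-SD estimates
  sqrt(E[cv^2 mu^2]) rather than cv·E[mu], so the whole-cohort CV estimate
  is inflated by the factor sqrt(1 + (sigma_b/mu)^2) relative to the
  generating within-stratum CV — about 1–2% at the default configurations.
- Covariate-adjusted (regression) CVs and interaction modelling are out of
  scope; stratification is the supported tool.
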