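# Methods

## The problem

During pregnancy the hypothalamic–pituitary–thyroid (HPT) axis is remodelled:
iodine demand rises, hCG transiently stimulates the thyroid, and the pituitary's
response to circulating free thyroxine (fT4) — its *central sensitivity* — may
shift. `thyrosens` implements an analysis of central sensitivity against iodine
nutrition in a pregnancy cohort: each measurement occasion contributes TSH
(μIU/mL), fT4 (ng/dL), anti-thyroid-peroxidase antibodies (anti-TPO, U/mL) and
spot urinary iodine (UI, μg/L), labelled with a gestational period (trimesters
T1–T3 by week: ≤13, 14–26, ≥27; PP = two months postpartum). Every row is
treated as an independent observation; no subject identifier is modelled, so
within-woman correlation is deliberately ignored (a known limitation of the
design, not of the implementation).

## The index

Central sensitivity is quantified by the Thyroid Feedback Quantile-based Index

    TFQI = cdf(fT4) − (1 − cdf(TSH)),

where `cdf` is the cumulative distribution function of each hormone over a
reference set. If feedback is intact, a sample sitting at the q-th quantile of
fT4 should sit near the (1−q)-th quantile of TSH and the terms cancel; a
positive TFQI means TSH is higher than the fT4 position predicts (reduced
sensitivity), a negative TFQI the opposite. The index is bounded in [−1, 1]
and invariant under strictly monotone transforms of either hormone.

Two empirical-CDF conventions are provided:

* `ecdf_leq` (default): F(x) = (#reference ≤ x)/n; the maximum maps to exactly
  1; ties share the "proportion ≤" value.
* `hazen`: (midrank − ½)/n; values lie strictly in (0, 1) and in a tie-free
  sample the cdf values average exactly ½, so the TFQI averages exactly 0.

The default reference set is the post-filter cohort pooled across all periods
(the index is defined over *all* analysed samples); per-period referencing is
available as a sensitivity analysis, and a reference can be frozen to JSON
(`EcdfReference`) to score new measurements prospectively. A parametric
variant (`parametric_tfqi`) with Gaussian fT4 and log-Gaussian TSH is offered
for scoring against published moments; it is a variant, not the primary
computation. fT4 is convertible ng/dL → pmol/L by the thyroxine molar-mass
factor 12.871.

## Outlier filtering

UI values — and only UI values — are screened with Tukey's IQR fence: values
strictly outside [Q1 − k·IQR, Q3 + k·IQR], k = 1.5 by default, are removed;
boundary values are retained. Quartiles use linear interpolation between order
statistics by default, with classic Tukey hinges as an alternative, and the
fence is fitted pooled across periods by default (per-period fitting is a
config switch). Rows with missing UI cannot be judged and are always retained.
Fencing precedes the TFQI, so the CDF reference set is the post-filter sample;
a `tfqi_prefence` switch reverses the order for sensitivity analysis.

## Iodine status

UI is classified into [0,100) deficient, [100,150) below the recommended
minimum, [150,250] optimal and (250,∞) high. Both 150 and 250 are assigned to
the optimal tier: the stratified analysis conditions on UI strictly *over*
250 μg/L, and the optimal band is described as *from* 150, so the boundaries
are inclusive on the optimal side. Cumulative proportions (<100, <150) are
reported alongside the four tiers.

## Inference

* **Stratified correlation.** Pearson r of TFQI (or TSH/fT4) against UI per
  period, restricted to UI above (strict) or at-or-below the 250 μg/L
  threshold. Two-sided p from the t transform with n−2 df. Strata with fewer
  than 3 complete pairs, or zero variance, are reported as not-estimable with
  their pair count rather than raised — sparse postpartum strata are expected.
* **Pairs bootstrap.** Whole (x, y) observations are resampled with
  replacement b = 1000 times; r is computed per replicate; replicates with a
  constant resampled variable are discarded and counted. Reported: the
  percentile 95% interval, the replicate mean (default summary; median
  optional) and the original-sample point r. Deterministic given a seed.
* **ANOVA.** One-way fixed-effects F tests of TSH, fT4, UI and TFQI across
  periods, with Tukey–Kramer (unequal-n studentized-range) post hoc
  comparisons. UI by anti-TPO positivity and period uses a two-way ANOVA with
  type II sums of squares (the design is unbalanced); the interaction is
  omitted unless requested and is dropped with a warning when a cell is empty.
* **Chi-square.** Anti-TPO positivity (level > 34 U/mL, strictly) by period,
  Pearson chi-square without continuity correction, with a warning when any
  expected count is below 5.
* **OLS.** Per-stratum, per-period least-squares lines for the scatter plots;
  a stratum with n < 2 or constant predictor yields a not-estimable fit, not
  an error.

Missing values are handled by pairwise deletion throughout: each analysis uses
the rows complete for the variables it needs.

## Synthetic cohorts

The generator emulates the study's data structure so the pipeline and its
statistical properties can be exercised without patient data. Per period it
draws n samples (defaults 438/274/364/26, the published per-period counts
scaled to the pre-filter total of 1102) from a Gaussian copula over latent
(fT4, TSH, UI) scores:

* **Marginals.** TSH and UI are lognormal with parameters moment-matched
  exactly to the published mean ± SD (σ² = ln(1 + sd²/mean²),
  μ = ln mean − σ²/2) — positive, right-skewed, the standard population shape
  for both; fT4 is Gaussian truncated at zero (its CV is small, so the
  truncation is negligible). Only the first two moments are constrained by the
  published summaries, so the families are a modelling choice and are the main
  respect in which the synthetic data may differ from the real cohort.
* **Dependence.** The latent correlation matrix is identity by default.
  A *stratum boost* b ∈ (−1, 1) re-mixes both hormone latents with the UI
  latent (z′ = b·z_UI + √(1−b²)·z) only for rows whose realised UI exceeds a
  threshold (250 μg/L), creating an above-threshold TFQI-UI association of
  either sign while leaving the unconditional marginals intact. This mimics a
  stratum-limited association phenomenologically; it claims no mechanism.
* **Calibration.** `calibrate_stratum_boost` bisects b against a Monte-Carlo
  oracle (`true_stratified_correlation`, default 10⁶ draws) so the population
  above-threshold correlation hits a requested value, e.g. +0.37.
* **Anti-TPO.** Positivity is Bernoulli per the period's rate, independent of
  everything else (matching a null TPO–iodine association); antibody levels
  are filled consistently with the flag but their within-class shape is
  arbitrary.
* **Contamination.** Extreme UI values can be injected (value × Uniform[4, 8]
  with probability `outlier_rate`) to stress the fence. The default rate is 0:
  the lognormal tail alone already places ~3% of UI values beyond the k = 1.5
  fence — slightly *more* than the ~2.5% removed in the real cohort — so extra
  contamination would overstate the filtering step. This is a marginal-shape
  limitation: the real UI tail beyond the fence is evidently lighter than
  lognormal, and consequently the synthetic above-250 strata retained after
  fencing (≈10–15 per period) are smaller than the real ones (≈29 in the
  second trimester), making single-cohort stratified correlations noisy.

Generation is bit-reproducible for a fixed seed.

## Validation experiments

The acceptance-style tests establish, at desk scale:

* exact agreement of quartiles, ECDF, Pearson r, F and chi-square statistics
  with independent brute-force (explicit counting/sums) oracles on hundreds of
  random instances, to 1e-10 relative error;
* the TFQI invariants (range, defining identity, monotone-transform
  invariance, monotone response in each argument) on randomised cohorts;
* 95% percentile-bootstrap coverage for ρ = 0.5, n = 30 bivariate Gaussian
  within [0.90, 0.98] over 500 Monte-Carlo repetitions at b = 1000;
* parameter recovery: with the boost calibrated to a true above-250 TFQI-UI
  correlation of ≈ +0.37 at second-trimester sample sizes, the analysis's
  bootstrap CI contains the true value in ≥ 90 of 100 generation–analysis
  repetitions. The repetitions deliberately exclude the fence step: the
  default generator injects no contamination, so there is nothing for the
  fence to remove by design, and fencing clean data would randomly truncate
  the stratum at each repetition's sample-dependent upper bound — every
  repetition would then estimate a slightly different quantity. A 500-run
  diagnostic measured coverage 0.92 without the fence and 0.83 with it, the
  deficit being entirely attributable to that estimand jitter rather than to
  the bootstrap;
* null behaviour: with an identity copula all stratified correlations stay
  within 3/√n of zero, and the correlation test's type-I error at nominal 0.05
  lies in [0.04, 0.06] over 10,000 simulations at n = 50.

Passing these shows the machinery is correct and calibrated *under the
generator's assumptions*; it cannot validate distributional features the
generator does not model (true marginal shapes, within-woman correlation,
assay error structure).

## Numerical choices and edge cases

* Anti-TPO positivity is strict: a level exactly at the 34 U/mL cutoff is
  negative.
* Fence boundary values are retained; an outlier is strictly outside a fence.
* ecdf ties: `ecdf_leq` gives tied values the shared "proportion ≤"; `hazen`
  uses mid-ranks.
* Bootstrap replicate correlations are clipped to [−1, 1] to guard against
  rounding just past the bound.
* Cohort CSV round-trips are lossless to at least 10 significant digits;
  missing values are empty cells, never zeros.
* Period labels win over gestational weeks when both are present and disagree
  (with a logged warning); weeks map ≤13 → T1, 14–26 → T2, ≥27 → T3.

## Known limitations

* The marginal families (lognormal TSH/UI) are assumptions; only two moments
  are matched. See the contamination note above for the practical consequence.
* No within-woman linkage, covariates (age, BMI, smoking) or
  gestational-week-resolved trajectories are modelled.
* The percentile bootstrap CI for a correlation is known to be slightly
  anti-conservative at very small strata (n ≲ 12); results for such strata
  should be read as descriptive.
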