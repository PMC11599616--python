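# Methods

## Reliability model

All reliability statistics derive from the two-way crossed ANOVA of an n×k
ratings matrix (rows = participants, columns = measurement methods, one
observation per cell): MSR (between participants, df n−1), MSC (between
methods, df k−1), MSE (residual, df (n−1)(k−1)). The single-measurement
variants follow the McGraw & Wong (1996) conventions:

* ICC(C,1) = (MSR − MSE) / (MSR + (k−1)·MSE). Invariant to adding a constant
  to any column; population value for k = 2 equals the Pearson correlation of
  the two channels under equal error variances.
* ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)). Penalizes
  systematic level differences between methods; from a column-mean-aligned
  matrix, any column shift lowers it. Note that from a *misaligned* matrix a
  shift that brings column means together can raise agreement — only
  consistency is shift-invariant in general.

Confidence intervals transform F-distribution bounds: the consistency CI from
F = MSR/MSE with (n−1, (n−1)(k−1)) df; the agreement CI via the
Satterthwaite-approximated denominator df (the full formula is written out in
`reliability.icc_agreement`'s docstring). Both variants are cross-checked
against an independent implementation (pingouin's ICC(C,1)/ICC(A,1) rows) and
against definitional sums of squares in the test suite.

Degenerate inputs: a constant matrix has no estimable ICC and raises
`DegenerateRatingsError`; MSE = 0 with positive row variance yields value 1
with a collapsed interval. Negative estimates are reported as computed and
banded "poor" (< 0.4; bands are half-open at 0.4 / 0.6 / 0.75). Complete-case
filtering happens inside `pairwise_consistency`, which logs the number of
dropped rows.

## Synthetic cohort

The generator emulates a large biobank extract: per participant and bilateral
region a latent volume T ~ N(mean, sd²) (left/right latents share a common
factor with configurable correlation, default 0.8), observed by two methods as

    X_m = T + offset_m + asym_m·s_h + Σ_c λ_{c,m}·z_c + e_m,
    e_m ~ N(0, σ_e²) independent,

with s_h = ±½ for left/right, λ the confound loadings (per SD of the
confound), and σ_e = sd·√((1−c)/c) inverting the target consistency c.
`hemisphere_asymmetry` shifts the latent left/right means (shared by both
methods); `method_asymmetry` gives each method its own left-minus-right
measurement shift, which is the mechanism for method × hemisphere
interactions. Phenotypes are Y = ρ·z(T) + √(1−ρ²)·ε with missingness
completely at random. Non-positive generated volumes are redrawn per cell and
logged; at the demo mean/SD ratios this affects a few cells in 10⁵.

Shared confound loadings add covariance between the channels, so the achieved
consistency exceeds the noise-only target; `empirical_checks` compares
achieved values against the model-implied ICC

    ICC_implied = 2(σ_T² + Σ λ₁λ₂) / (var X₁ + var X₂)

and flags deviations beyond 3 Monte-Carlo SEs. What the generator does *not*
emulate: image-level segmentation, non-Gaussian or heteroscedastic volume
differences, site/scanner batch structure beyond linear loadings, and
informative missingness. Passing tests therefore certify the statistical
machinery under the additive-Gaussian model, not distributional realism of
any particular dataset.

### Demo configuration

`configs/demo.yaml` defines the study conditions used by the analysis drivers
and the acceptance script: 20,000 participants; amygdala (mean 1500 mm³, SD
200 mm³) with target consistency 0.2, hippocampus (3800 mm³, SD 350 mm³) at
0.65 — the poor-vs-good contrast of interest; four confounds led by a shared
head-size loading; ten phenotypes with true correlations spanning 0–0.15 and
varied missingness. The amygdala's method asymmetries (+18 / −87 mm³) were
sized analytically from the model's pooled SD (≈ 457 mm³) so the planted
standardized left-right contrasts are ≈ +0.04 and ≈ −0.19 (interaction
≈ 0.23), emulating a realistic opposite-lateralization disagreement; a test
verifies the analytic pooled SD against the generated data.

## Structural comparisons

* **Orthogonal regression**: Deming estimator with error-variance ratio δ
  (default 1 = total least squares); slope is the principal axis of the 2×2
  covariance, line through the means. An exactly vertical fit raises rather
  than returning an infinite slope.
* **Proportional difference**: (v₁ − v₂)/((v₁+v₂)/2); the per-region summary
  pools hemispheres and reports the mean cross-method average volume and the
  SD of the proportional difference, sorted by size. Under equal absolute
  disagreement smaller structures show larger proportional variability.
* **Contrasts**: the four (method, hemisphere) columns of a region are
  standardized against the pooled four-column mean/SD — per-column
  standardization would erase the mean differences under test — then
  left−right per method and the double difference (the interaction) are
  paired t-tests on per-participant differences. Mixed-effects alternatives
  are out of scope.
* **Residualization**: OLS on confounds plus intercept, per volume column;
  idempotent, zero-mean residuals, rank-deficient designs rejected. Whether
  residualization raises or lowers cross-method consistency is empirical: a
  confound loading on *both* methods contributes shared variance, so removing
  it lowers apparent consistency (demonstrated in the tests and the
  `icc_residualized.csv` output).

## Discordance simulations

Triplets (X₁, X₂, Y) follow the unit-variance latent model described in the
README; this is the minimal construction with pre-specified population
consistency ICC between measurements and corr(X_m, Y) = ρ·√ICC. Correlation
tests are two-sided with significance strictly p < α (default 0.05); the
per-experiment path uses scipy's pearsonr/spearmanr, and the vectorized batch
engine computes r row-wise with t-approximation p-values — a test pins the
two paths to each other at 1e-12. Spearman is Pearson on mid-ranks with the
same t approximation.

Experiments are classified into four categories (none significant / exactly
one / both same sign / both opposite sign); an exactly-zero coefficient in a
both-significant pair counts as same-sign (a measure-zero event under
continuous sampling). Conflict rates are conditional proportions; uncertainty
is the median and 2.5th/97.5th percentiles of per-batch rates, excluding (and
counting) batches with zero denominator. Per-cell RNG seeds are derived by
hashing (base seed, icc, rho, n), so extending a grid never perturbs existing
cells.

Problem sizes: grid cells default to 200 batches × 500 experiments (the demo
config uses 100 × 200 for the 30-cell grid). At ICC 0.2, ρ 0.1, n 50 the
both-significant denominator is ~3 per 500-experiment batch, making the
per-batch sign-conflict rate highly discrete (median 0); where a stable
sign-conflict estimate is reported (the acceptance script), that cell is run
with 5,000-experiment batches instead.

## Cohort resampling

Screening computes Spearman correlations between each phenotype and the
cross-method average volume on pairwise-complete observations, keeps the
top-k by absolute value, then restricts to strict complete cases over those k
variables. Each experiment draws n participants without replacement
(independently across experiments) and evaluates *all* selected variables on
the same draw, reusing the discordance classifier so both pipelines share one
definition of conflict. Defaults: top_k 50 (10 in the demo, matching its
phenotype count), n ∈ {50, 100}, 50 batches × 200 experiments at desk scale.
The sample-size comparison table flags variables whose sign-conflict rate
increased at the larger n.

## Reporting

Estimates render as `value [lo, hi]` with fixed digits (round-half-even).
Output CSVs are UTF-8, LF, header row, no index; pipelines and the CLI write
a JSON manifest (command, config hash, seed, version, timestamps, outputs).
All randomness flows from `numpy.random.default_rng` seeded per stage by
hashing the master seed with the stage label, so `run-all` is byte-identical
across reruns with the same seed.

## Known limitations

* Equal error variances for the two methods are the default (an
  `error_sd_ratio` knob exists for sensitivity analyses); real tools likely
  differ in error variance and in non-additive ways.
* The agreement CI's Satterthwaite approximation can be slightly anticonservative
  for very small n and large method offsets.
* Conflict-rate uncertainty comes from batch percentiles, not analytic
  binomial intervals, so interval resolution is limited by batch count.
* The resampling study treats phenotypes as jointly observed after the
  complete-case restriction; selection effects from informative missingness
  are not modeled.
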