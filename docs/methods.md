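# Methods

## The two-sample MR model

Each analysis relates one gut-microbiota taxon (exposure *X*) to BMD at one
skeletal site (outcome *Y*) through k independent SNPs. The working model
for true per-allele effects is

    Gamma_j = beta * gamma_j + alpha_j

where `gamma_j` is the SNP→exposure effect, `beta` the causal effect of
interest and `alpha_j` a direct (pleiotropic) SNP→outcome effect. Observed
effects are `gamma_hat_j ~ N(gamma_j, se_exp_j)` and
`Gamma_hat_j ~ N(Gamma_j, se_out_j)` from non-overlapping GWAS samples.
Valid instruments require `alpha_j = 0`; the sensitivity battery probes
departures.

Exposure and outcome effects are treated as unitless per-allele effects on
standardized traits. The heel-BMD source expresses effects in SD of
ultrasound-estimated BMD rather than g/cm²; since MR estimates are
invariant to a common rescaling of the outcome, no conversion is attempted
and all betas are handled identically.

## Estimators

* **Wald ratio** (k = 1): `beta = Gamma_hat/gamma_hat`, first-order
  delta-method SE `se_out/|gamma_hat|`. The exposure-side noise is ignored,
  the convention consistent with single-SNP rows in published tables; with
  F ≈ 13 or more the neglected term is second-order.
* **IVW**: inverse-variance weighted mean of ratios, identical to weighted
  zero-intercept regression of `Gamma_hat` on `gamma_hat` with weights
  `1/se_out^2`. Default is multiplicative random effects — the FE standard
  error scaled by `max(1, sqrt(Q/(k-1)))` — conservative under
  heterogeneity and identical to FE when Q ≤ df. With k = 1 it reduces
  exactly to the Wald ratio.
* **MR-Egger**: weighted least squares with free intercept after orienting
  all pairs to `gamma_hat >= 0` (Egger is not orientation-invariant; this
  is the standard convention). Coefficients come from explicit normal
  equations; the residual variance scale is floored at 1, matching the
  reference formulation. Intercept and slope are tested with two-sided
  normal tests; for a numerically exact fit the zero-intercept case reports
  p = 1.
* **Weighted median**: ratios sorted ascending, normalized inverse-variance
  weights `w_j`, partial sums `S_j = sum_{i<=j} w_i - w_j/2`, estimate by
  linear interpolation at S = 0.5. SE from a seeded parametric bootstrap
  (ratios resampled from `N(r_j, se_rj)`, 1000 replicates by default).
* **Weighted mode**: argmax of a weighted Gaussian KDE over ratios on a
  512-point grid. Bandwidth is `bandwidth_factor * 0.9 * min(sd, mad) *
  k^(-1/5)` with MAD scaled by 1.4826; a degenerate (zero-spread) ratio set
  short-circuits to the common value. SE by the same seeded bootstrap.
* **Reporting**: OR = exp(beta); CI bounds use the exact 0.975 normal
  quantile (1.959964…), not 1.96 — the difference is below reporting
  precision. Table output formats beta/SE with 3 significant digits in
  scientific notation, OR/CI at 3 decimals (round half away from zero), p
  at up to 4 decimals switching to scientific below 1e-4.

## Sensitivity diagnostics

* **Cochran's Q** over ratio estimates about a reference slope (default:
  the FE-IVW estimate, which minimizes Q); chi-square with k−1 df.
  Heterogeneity is declared at p ≤ 0.05; the pipeline warns and proceeds
  rather than halting.
* **MR-PRESSO**: the observed residual sum of squares uses leave-one-out
  IVW slopes (each SNP's residual about the fit excluding it), weighted by
  `1/se_out^2`. The null distribution comes from parametric simulation
  (n_sim = 1000 by default, seeded): `beta_exp* ~ N(beta_exp_j, se_exp_j)`,
  `beta_out* ~ N(slope_-j * beta_exp_j, se_out_j)`. Empirical p-values use
  the (1 + count)/(1 + n_sim) convention so they are never exactly zero.
  Per-SNP outlier p-values are Bonferroni-adjusted by k and only evaluated
  when the global test is significant; on outlier removal the estimate is
  recomputed and a distortion p-value obtained by removing equally many
  random inliers. All leave-one-out slopes are computed vectorized in
  closed form, so 500–1000 simulations cost milliseconds.
* **Leave-one-out**: IVW recomputed without each SNP (Wald ratio when one
  SNP remains); a SNP whose omission flips the sign of the estimate is
  flagged, excluded, and the analysis rerun — the influence rule used on
  the published leave-one-out plots.
* **Steiger directionality**: per-SNP variance explained is derived from
  the Wald t statistic, `r2 = t^2/(t^2 + n - 2)`, summed over instruments
  per trait. The t-based form is used instead of the allele-frequency form
  because effect-allele frequencies are missing from some consortium files.
  Direction is "correct" when `r2_exp > r2_out`; the p-value is a
  two-sample z test on Fisher-transformed |r| with variances 1/(n−3).
  Analyses failing the test are excluded from result tables and logged.
* **Pleiotropy screen**: the Egger intercept test at the 0.05 level gates
  confounder-SNP exclusion (a local snp→trait table, e.g. a curated
  PhenoScanner export) followed by re-analysis.

## Instrument selection

Dual thresholds mirror study practice: genome-wide 5e-8, and a looser 5e-6
screen because few taxa yield genome-wide-significant SNPs. Clumping is
greedy — best remaining p-value wins, ties broken by (chrom, pos, snp_id)
for determinism — with r² < 0.01 within 10,000 kb. The LD source is an
injectable pairwise lookup; without one, clumping is distance-only (every
SNP within the window of an accepted SNP is removed), which needs no
reference panel and is exact for the generator's widely spaced variants.
The F filter applies the strict reading of the F < 10 rule: F = 10 is kept.

## Harmonization

Alleles resolve in order: exact match (copy), swapped (negate beta_out,
eaf → 1−eaf), strand complement, complement-plus-swap; anything else drops
as `allele_mismatch`. Palindromic SNPs (A/T, G/C) drop unconditionally —
no frequency rescue by default, matching study practice — and multiallelic
records drop as `multiallelic`. SNPs absent from the outcome GWAS are
dropped and counted (no proxy lookup). Every drop carries a reason, and the
pipeline audit accounts for each input SNP exactly once per analysis.

## Synthetic data generator

The generator emulates the two-sample structure the pipeline targets:
exposure GWAS n = 18,340; outcome GWAS n per site (32,735 femoral neck,
8,143 forearm, 28,498 lumbar spine, 426,824 heel). Defaults: 30 SNPs per
taxon, MAF ~ U(0.05, 0.5), per-SNP exposure heritability 0.002 (mean
F ≈ 1 + n·h² ≈ 38, the strong-instrument regime), causal effect 0.1, no
pleiotropy. Standard errors follow the standardized-trait approximation
`se = 1/sqrt(2 maf (1-maf) n)`. Pleiotropic effects are defined relative to
the exposure-increasing allele (multiplied by sign(gamma) internally);
without this convention a nonzero pleiotropy mean would cancel under random
allele coding and "directional" pleiotropy would be indistinguishable from
balanced. Planted outliers add `outlier_scale * se_out` (random sign) to a
random SNP's pleiotropic effect; a weak-instrument fraction rescales gamma
to a target F of 4; a palindromic fraction assigns A/T or G/C alleles.
Positions are spaced 20,000 kb apart per chromosome so default clumping is
neutral unless configured otherwise.

What the generator does **not** emulate: LD between instruments (clumping
is exercised with hand-built position/LD tables), cross-taxon correlation
(taxa are independent), sample overlap between the two GWAS, population
stratification, and 16S abundance-level noise. Passing calibration tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data complications.

## Published-table consistency checking

The five bundled result tables carry printed (beta, SE) pairs and derived
OR/CI/p cells. Strict recomputation at printed precision matches only
about half the cells, because the journal's derived cells were computed
from more digits of beta/SE than were printed, and the display convention
mixes round-half with truncation. `check_tables` therefore also propagates
the 3-significant-digit rounding interval of beta and SE through each
derived quantity (all are monotone in both arguments, so interval ends sit
at corners) and accepts a cell when the feasible interval overlaps the
printed cell's own representation interval. Under this precision-aware
test all 61 rows are consistent. One genuine inconsistency exists in the
bundled tables and is surfaced by `q_df_consistency()`: a lumbar-spine
family row reports 5 SNPs with q_df = 1 instead of 4.

## Multiple testing

Bonferroni thresholds are 0.05/n per taxonomic level, with n the number of
taxa actually analyzed (instruments survived selection) at that level.
Comparisons always use the exact quotient; the two-significant-figure
rounding is display-only. Nominal (p < 0.05) and Bonferroni-surviving flags
are both carried on every result row.

## Determinism and problem sizes

Every stochastic component (bootstrap SEs, MR-PRESSO simulations, the data
generator) takes an explicit seed, and output files contain no timestamps,
so a rerun with the same config is byte-identical. The calibration suite
uses 1000 seeds for IVW recovery/coverage (50 SNPs each), 1000 replicates
for Q-test type-I error, 200 seeds × 500 simulations for MR-PRESSO outlier
recovery, and 300 seeds for Steiger directionality — sizes chosen to make
binomial noise on the checked proportions small relative to the asserted
bands while the whole suite stays interactive (tens of seconds).

## Known limitations

* Distance-only clumping is exact only when true LD does not extend beyond
  the window; with a real reference panel, supply an `ld_lookup`.
* No proxy-SNP recovery for instruments missing from the outcome GWAS.
* No SIMEX correction for Egger, no multivariable MR, no FDR alternatives
  to Bonferroni (a config hook is reserved).
* The Egger intercept test uses the normal approximation; with very few
  instruments a t reference would be more conservative.
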