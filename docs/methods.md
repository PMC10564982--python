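# Methods

This note records the statistical model behind `hrpfnorms`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical decisions a maintainer should know about.

## The Box-Cox Cole–Green (LMS) reference model

Within one indicator, sex and whole-year age group, measurements `x > 0`
follow the BCCG distribution with parameters λ (Box-Cox power), μ (median)
and σ (coefficient-of-variation-like scale). The Box-Cox deviate

    z = ((x/μ)^λ − 1)/(λσ)    for |λ| ≥ 1e-7,   z = ln(x/μ)/σ otherwise

is standard normal, truncated to the region where the power transform is
defined (`1 + λσz > 0`). Choices:

- **λ = 0 branch threshold `1e-7`.** Published triples go as low as
  λ = −0.004 and must use the power branch: at the P90 of the 13-year-old
  boys' grip reference the power branch gives 44.86 where the log branch
  would give 44.83. Double precision keeps the power branch stable down to
  |λ| ≈ 1e-7.
- **Truncation.** The density includes the truncation constant
  Φ(1/(σ|λ|)) so that it integrates to one; sampling draws the deviate from
  the correspondingly truncated normal. For every published triple the
  truncation mass is negligible (<1e-4), but band-implied distributions can
  be skewed enough that it matters — see "support bounds" below.
- **Centile inversion** uses the plain LMS relation
  `X_p = M(1 + LSz_p)^(1/L)` with full-precision normal quantiles, raising
  a domain error when the requested centile falls outside the Box-Cox
  support. This is the standard reference-curve relation; reproducing the
  published tables requires it verbatim.
- **Rounding.** Table cells and band edges round half-up (ties away from
  zero) to 2 decimals, the convention of printed norm tables; MAPE rounds
  half-up to 3 decimals. Classification always uses unrounded totals.

## Fitting

Per-group triples maximise the BCCG log-likelihood over (λ, ln μ, ln σ)
(log parameterisation enforces positivity) with Nelder-Mead, starting from
λ = 1, the sample median, and a MAD-based robust CV; convergence is a
relative log-likelihood change below 1e-8 within 500 iterations, and
non-convergence is flagged, never silently replaced by the start. Groups
need ≥30 observations (configurable); an all-equal sample raises a
scale-collapse error.

**Support bound during fitting.** The optimiser rejects σ|λ| > 0.5.
Beyond that the Box-Cox support no longer contains ±2 SD, so the fitted
triple could not define the outer reference centiles (P3/P97) the system
is built from — and the truncation-corrected likelihood otherwise admits
degenerate, heavily truncated modes (observed on strongly skewed pull-up
samples). The bound is far above every realistic fit (published triples
peak at σ|λ| ≈ 0.27).

**Age smoothing.** Curves across ages 12–16 are either independent per-age
fits (the default) or a penalised joint fit with squared-second-difference
roughness penalties on the λ, μ and σ age series; in the large-penalty
limit each series becomes linear in age. With only five whole-year age
groups and sizeable cells, independent fits are already smooth in
practice, hence default penalties of zero; penalties are exposed as plain
weights rather than effective degrees of freedom because five support
points do not warrant the heavier machinery. Ages are integer groups, not
a continuous covariate.

## Grade bands

Fitness indicators use the five-grade percentile scheme — Very poor
[P3, P10] = 1, Poor (P10, P35] = 2, Medium (P35, P65] = 3, Good
(P65, P90] = 4, Excellent > P90 = 5 — realised as closed intervals on
2-decimal values with each band starting 0.01 above the previous edge, and
no score below P3 (the published minimum-score line). BMI uses lean
[P5, P15] = 1, normal = 5, overweight = 3, obese above P95 = 1; BMI has no
minimum line, so values below the lean band still grade lean. The lean
band's upper edge at P15 follows the published band table (whose layout is
the operational standard) rather than the looser "≤P5" phrasing that
accompanies it; the cut is configurable. Band resolution is configurable
per indicator (powers of ten).

## Back substitution

The cross-validation refits the norms on a random subsample — default 20%,
stratified by age × sex, drawn without replacement — and compares the
subsample's fitted medians (P50 = μ) to the full-sample medians by
MAPE = |actual − fitted|/actual, with the full-sample value as "actual".
The subsample fraction is a package default (the original procedure's
fraction is not published); reports carry per-age rows plus the arithmetic
mean of the raw row errors. No pass/fail bound is imposed by default; a
config bound is available.

## AHP weighting

Weights come from positive reciprocal judgment matrices via normalised row
geometric means; consistency uses λ_i = (Cw)_i/w_i, λ_max = mean(λ_i) (the
standard estimator matching the per-row form; "max" is a misnomer kept by
convention), C.I. = (λ_max − m)/(m − 1), threshold 0.1 with no
random-index stage. Reciprocity validation uses a 1% relative tolerance,
enough to absorb printed-table rounding (2.44 vs 1/2.444). Of note, the
built-in 4×4 fitness judgment matrix evaluates to C.I. ≈ 0.113 under its
own geometric-mean weights — slightly above the usual 0.1 bound — which is
one reason the pipeline's default composite weights are the published
expert-adjusted scheme (summing to 0.9958, kept as published) rather than
weights derived from the matrices; the purely computed hierarchical AHP
scheme remains available via configuration.

## Composite scoring

The total is the weighted sum of scored indicators. When an indicator is
unscored (missing measurement, or a fitness value below P3) it is dropped
and the remaining weights are scaled back up to the scheme's original
weight sum, with the record flagged; the alternative of emitting no
composite is available by configuration. Totals live in (0, 5] and map to
Very poor (<1.5), Poor, Medium, Good and Excellent (≥4.5, including a
perfect 5), on half-open bands with the unrounded total.

A note on the published worked example: its stated scores and coefficients
yield 2.2668, while the published text prints 2.247. The two are
arithmetically incompatible; the package reproduces the formula and the
resulting category (Poor), not the printed total.

## Synthetic cohort

The generator emulates the study design behind the published norms: three
districts × 20 schools × 50 students (ages 12–16 at ~20% each, sexes
50/50), with round(1%·N) nonresponders removed uniformly at random — 3,000
generated, 2,970 retained at the defaults. Allocation within each school
is balanced (exact age blocks and sex split, randomly paired) rather than
independently random: the study's demographic table shows near-exact
balance, and balanced allocation reproduces that pattern with the
generator's realised shares always inside 19–21% per age and 49–51% per
sex. Nonresponse is unclustered because no structure is published.
Measurements are recorded at 0.01 resolution (floored at 0.01).

Ground-truth distributions: BMI and hand grip draw from the published LMS
triples directly. The three indicators whose norms are published only as
grade bands (pull-up, plank, shuttle VO₂max) draw from triples recovered
from the band edges: the P10/P35/P90 edges give three equations solved
exactly by 1-D root-finding in λ (the power-branch residual is divided by
λ to remove its spurious sign change at zero; brackets are scanned on
[−15, 15]). A minority of published band rows are so skewed that the exact
solution's support would exclude P3 and truncate several percent of the
sampling mass; those rows fall back to a least-squares fit over all five
published edges constrained to σ|λ| < 0.37 (support covering P0.3–P99.7),
reproducing their edges within about 9% instead of exactly. Indicators are
drawn independently by default (no correlation structure is published);
for stress testing, a Gaussian-copula correlation matrix across the five
indicators can be supplied in the cohort config. Independence mainly
narrows the spread of composite totals relative to a correlated
population.

What passing tests on this cohort do **not** show: agreement with the
original survey's cohort-level grade distribution (the raw data are not
deposited), realistic school-level clustering, device measurement error,
or integer-valued pull-up counts (values are continuous on the modelled
scale).

## Problem sizes used in the test suite

Deterministic table checks run on the published triples directly.
Stochastic checks use: parameter recovery at n = 500/group over 20 seeds
(median errors: μ ≤ 2%, σ ≤ 10%, λ ≤ 0.3); the grade-mass law on 10⁴
draws against a 3-binomial-SE envelope; back-substitution stability on the
2,970-record default cohort over 20 subsample seeds; and curve recovery at
n = 300/age. These sizes mirror the study's own cell sizes (~300 per
age/sex cell).

## Known limitations

- The BCCG family cannot represent all published band rows exactly (see
  the fallback above); band-implied ground truth is an approximation for
  those rows.
- Five age points fit near-independently; the smoothing penalties are
  provided but unexercised by default.
- The shuttle-run indicator is handled on whatever unit the cohort file
  supplies (the published bands are on estimated VO₂max); no laps→VO₂max
  conversion is attempted, and unit consistency between cohort and curve
  is the caller's responsibility.
- Single-split back substitution only; the repeat-over-seeds helper in the
  test suite is a stability probe, not a k-fold scheme.
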