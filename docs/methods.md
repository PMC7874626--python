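# Methods

This note records the scoring model as implemented, the conventions
chosen where the program rules are underspecified, what the synthetic
cohort generator does and does not emulate, and known limitations.

## The scoring model

For each fiscal year FY ∈ {2015, …, 2018} a `MethodologyConfig` fixes
five things: the PSI-90 weight column, the Domain 2 measure set, the
scoring method, the domain weights, and the treatment of hospitals with
no Domain 2 data.

**Domain 1 (PSI-90 composite).** With weight column *w* and component
ratios *r*, the composite is Σᵢ wᵢ rᵢ / Σᵢ wᵢ over the components
present in both the record and the column. The four published columns
are stored exactly as printed (four decimals; column sums 1.0000,
0.9994, 1.0000, 0.9998) and never renormalized at load time. For FY2015
and FY2016 two columns exist — with and without present-on-admission
(POA) reporting; the registry defaults to the POA column (the kind of
discharge data the retrospective design assumes) and the other is
selectable per config. A note on the primary sources: the prose
description of the domain weights (35/65, 25/75, 15/85, 15/85 for
Domain 1/Domain 2) and the tabular summary print the same numbers under
swapped labels; this package follows the prose, which matches the
program's documented trajectory of increasing Domain 2 emphasis. The
discrepancy is flagged here rather than silently resolved.

**Missing components.** A hospital missing some PSI components is scored
on the ones it has, with weights renormalized over that subset; the
result carries a `renormalized` flag. The alternative — treating missing
components as zero — would reward non-reporting. A hospital with no
overlapping component at all is "Domain 1 unscorable" and falls through
to 100% Domain 2 weight (or to the skip-list if it has no Domain 2
either). Whether CMS renormalizes or excludes such hospitals is not
documented in the sources used; the choice is surfaced, not hidden.

**Decile scoring (FY2015–17).** Each measure maps to an integer 1–10:
`decile = ⌈10·r/n⌉` where `r` is the max-rank (number of eligible values
≤ own value). Ties therefore share the *worse* decile, which is
deterministic, conservative, and makes the all-tied cohort well defined
(everyone lands in decile 10). Domain 1 is the decile of the composite;
Domain 2 is the unweighted mean of per-measure decile points over the
measures a hospital reports, each measure deciled among its reporters
only. The program's description of Domain 2 ("based on the average of
reported SIRs") is ambiguous between *average the deciles* and *decile
the average*; this package averages per-measure decile points, which
keeps the score in [1, 10] regardless of which measure subset a hospital
reports. The alternative reading would rank hospitals that report
different measure subsets on incommensurable averages.

**Winsorized z-scores (FY2018).** Per measure, values are capped at the
empirical 5th/95th percentiles over the reporting hospitals, then
standardized: z = (clamp(x, p₅, p₉₅) − μ_w)/σ_w with μ_w, σ_w the mean
and sample SD (n−1 denominator) of the *winsorized* values. Domain 1 is
the winsorized z of the composite under the same convention; Domain 2 is
the unweighted mean of per-measure z's (measure-level weighting of
z-scores is a later program change, out of scope). The observed range of
total scores (roughly −3 to +3) is an empirical consequence, not an
enforced clamp. A measure whose winsorized values are constant cannot be
standardized and raises a degenerate-measure error naming the measure.

**Percentile convention.** Throughout the package the p-th percentile of
n ascending values is the order statistic at position ⌈p·n⌉ (1-indexed).
With n = 1704 distinct totals the 75th-percentile cutoff is the 1278th
value and exactly 426 hospitals lie strictly above it — the size of the
penalized quartile in the emulated study sample. The sample SD uses the
n−1 denominator.

**Totals and penalties.** Total = w₁·D1 + w₂·D2 with both domains
present; 100% weight on the present domain otherwise. Hospitals with no
Domain 2 data are handled by one of two modes, mirroring the two
analyses the retrospective design requires: `exception` (assume the HAI
exception: score on Domain 1 alone) and `max_score` (assume no
exception: impute the maximum Domain 2 score — 10 points under the
decile method, the cohort's maximum *observed* Domain 2 z under the
winsorized method, computed before imputation; a theoretical cap does
not exist for a z-score). A per-hospital `hai_exception` flag overrides
`max_score`. Penalty: strictly above the threshold ("above the 75th
percentile"), so hospitals exactly at the cutoff are not penalized, and
an all-tied cohort penalizes nobody. Percentiles are always computed
within the input cohort, never against external national cutoffs. The 1%
payment reduction is represented as a boolean flag only.

Note one asymmetry between the modes: under the decile method the
imputed 10 is the global maximum of the score scale, so switching
`exception` → `max_score` can only raise the total of a hospital lacking
Domain 2. Under the winsorized method the imputed value is the cohort
maximum of *Domain 2*, which can lie below a hospital's Domain 1 z, so
its total can move either way. Fully reporting hospitals' scores are
identical under both modes; only the threshold moves.

**Comparison.** Penalty-set overlap is 100·|A∩B|/|A| with the common
per-methodology set size as denominator; with ties the sets can differ
in size, in which case the larger size is used and a warning logged. The
all-methodologies figure uses the same convention on the intersection of
all sets, so it is bounded above by every pairwise overlap. Rank-shift
summaries report the Spearman correlation of totals, the mean and max
absolute change in max-rank percentile, and the number of hospitals
crossing the 75th-percentile boundary in either direction.

## The synthetic cohort generator

Defaults (one per line, chosen to emulate the study sample's structure):

| parameter | default | meaning |
|---|---|---|
| `n_hospitals` | 1704 | hospitals with scorable Domain 1 |
| `frac_domain2_reporting` | 1105/1704 ≈ 0.648 | P(report ≥1 Domain 2 measure) |
| `reporting_probs` | CLABSI .85, CAUTI .90, SSI .70, MRSA .80, CDI .85 | per-measure reporting among reporters |
| `latent_quality_sd` | 0.3 | SD of the shared log-scale quality factor (0 disables it) |
| `measure_noise_sd` | 0.4 | idiosyncratic lognormal scale of each SIR |
| `psi_component_lognormal_params` | (0, 0.4) each | per-PSI log-location/scale |
| `icu_ward_noise_sd` | 0.35 | additive noise between CLABSI/CAUTI surveillance scopes |
| `tie_fraction` | 0.1 | fraction of values rounded to 1 decimal |
| `seed` | required | no implicit entropy |

Each hospital draws a latent quality deviation q ~ N(0, latent_sd²); a
measure's log-value is its location + q + scale·ε. The lognormal form
reflects that PSI ratios and SIRs are nonnegative, right-skewed
observed-to-expected ratios centered near 1. The ICU+ward CLABSI/CAUTI
variant is the ICU-only value plus N(0, icu_ward_noise_sd²) noise,
truncated at 0; the default noise scale is anchored to the published
cross-scope prediction errors for these measures (RMSE 0.30–0.40), as a
calibration anchor rather than a validation target — the generator emits
both scopes directly instead of reproducing that prediction model. A
reporter that draws no measure is assigned CAUTI (the most commonly
reported). Ties are injected by rounding because tie handling is a
primary test surface. The latent SD is permitted to be exactly 0 so the
no-shared-quality regime is testable; all other noise scales must be
strictly positive.

**What the generator does not emulate.** Real PSI components have
heterogeneous variances and a low-rank correlation structure that the
equal-scale, single-factor default does not encode; distributional
summaries of the study's inputs were not available to calibrate against,
so the defaults are stylized. One observable consequence: with
equal-scale components sharing one factor, any two heavily overlapping
weight columns produce near-collinear composites, so swapping the PSI
weight column alone churns the penalty set less here than it did in the
real program data, where Domain 1 recalibration was the dominant source
of penalty churn. Passing tests on this generator therefore demonstrate
the correctness of the scoring arithmetic and the qualitative machinery
of the comparison — not the empirical magnitudes of methodology
sensitivity in real hospital data. Geography, hospital covariates and
claims-level discharge records are likewise out of scope.

The fixed 12-hospital worked micro-cohort covers every edge case by
construction (missing components, a PSI-07-only hospital, no-Domain-2
hospitals with and without the HAI exception, ties, a winsorization-cap
outlier); its expected scores under all four methodologies and both
missing-data modes were computed once with independent brute-force
oracles and frozen as a JSON fixture in the test suite.

## Numerical choices and degenerate inputs

* Deciles and thresholds use exact integer arithmetic on max-ranks
  (`⌈10r/n⌉` computed as `-((-10r)//n)`), so there is no floating-point
  tie-breaking.
* Penalty assignment requires n ≥ 4 (a quartile of fewer hospitals is
  not meaningful); winsorization requires n ≥ 2 and a non-constant
  vector.
* Cohort CSVs round-trip at full float precision; scored and comparison
  tables are written at fixed 6-decimal precision, sorted by hospital
  id, so repeated runs are byte-identical and diff cleanly.
* All pipeline stages are deterministic functions of inputs and config;
  the only randomness in the package is the generator's seeded RNG.

## Problem sizes

The default cohort is the study-scale n = 1704. The test suite
exercises the pipeline at cohort sizes 100–800, the oracle-equivalence
suites at n ≤ 200 over hundreds of random tied cohorts, and the
generator's percentile-recovery check at n = 20000; these sizes give
stable statistics while keeping the suite fast.

## Known limitations

* FY2019+ rule changes (re-adjusted Domain 1 weights, equal domain
  weighting, weighted z-scores) are not modeled.
* PSI component results are taken as given risk-adjusted ratios; the
  AHRQ software's claims-level computation, smoothing, and the severity
  index behind the 6.0.2 weights are upstream and out of scope.
* Whether the FY2018 maximum-z imputation used a fixed constant or the
  cohort maximum is not documented; the cohort maximum is used (no
  finite theoretical maximum exists for a z-score).
* Penalty dollar amounts, hospital-characteristic regressions and
  statistical inference on overlap differences are out of scope; the
  comparison is descriptive.
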