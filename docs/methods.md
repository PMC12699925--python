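# Methods

## Model and scope

The package analyses cohorts of two-arm parallel-group superiority trials.
Designs outside that frame (single-arm, crossover, cluster-randomised,
group-sequential, adaptive) are out of scope: their sample-size formulae are
not the simple two-sample form inverted here, and records describing them
should be excluded upstream.

All effects live on the standardised (Cohen's *d*) scale. Three routes put a
*target* there, in fixed priority:

1. **direct** — continuous outcome with a stated raw difference Δ and SD:
   δ = Δ/SD;
2. **converted** — binary outcome with both event rates (via the odds ratio)
   or time-to-event outcome with a hazard ratio: δ = |ln ratio|·√3/π. The
   factor √3/π comes from the standard-logistic variance π²/3: a log-odds
   difference divided by π/√3 is a difference in standard-deviation units.
   The arcsine transformation is a defensible alternative for binary
   outcomes; the logistic conversion is used because it treats odds and
   hazard ratios identically and is the convention in effect-size
   standardisation across outcome types;
3. **back-calculated** — otherwise, δ = (z₁₋α/ₛ + z₁₋β)·√(1/n₁ + 1/n₂),
   the inversion of the normal-approximation two-sample sample-size formula.
   It is used for all outcome types, because it is the only universally
   invertible form: the back-calculated δ is a composite of the hypothesised
   effect and the assumed variability, which is precisely what makes targets
   comparable.

When a direct target and a back-calculated one are both computable the direct
value is used and the back-calculated value is kept as a consistency
diagnostic (`consistency_mismatch`, default tolerance 0.2 on the d scale);
gross disagreement between what a protocol says it targets and what its
sample size implies is a candidate calculation error.

A superiority target of exactly zero is invalid and raises. Observed effects
may be zero or negative: signs are positive in the hypothesised direction,
and reversals carry a negative sign, which inflates the discrepancy — the
correct behaviour, since a trial whose result went the wrong way was at least
as overpowered by optimism as one whose result was merely null.

*Observed* effects dispatch most-information-first: raw effect with pooled SD
(continuous) or ratio estimate (binary/time-to-event), then a test statistic
with achieved per-arm sizes (d = z·√(1/n₁+1/n₂)), then a p-value with
achieved sizes (z = Φ⁻¹(1−p/s)). A continuous effect reported with an SE but
no pooled SD routes through the implied z = effect/SE. t statistics with
df ≥ 30 are treated as z; below 30 they are converted through the t CDF to a
p-value first, because small trials are exactly where the distinction
matters. The fixed priority makes results reproducible when several summary
forms coexist.

## Defaults and assumptions

Missing α defaults to 0.05 and missing sidedness to two-sided — the only
defaults applied anywhere, mirroring how such gaps are resolved in practice
(and checkable against each trial's publication). Power has no default.
Every applied default and assumption (attrition deflation, assumed effect
direction) is recorded in the effect's `assumptions_applied` and echoed once
per trial in the run log.

Attrition convention: enrolment = evaluable/(1−a); when only the enrolment
total is recorded, evaluable = ⌊enrolment·(1−a)⌋. Protocols are not uniform
on this convention, so the applied choice is always recorded per trial.

Per-arm sizes are derived from a total by taking the largest n₁ whose
ratio-consistent pair (n₁, ⌈r·n₁⌉) fits the total. This exactly inverts the
forward construction n₁ = ⌈(z_α+z_β)²(1+1/r)/δ²⌉, n₂ = ⌈r·n₁⌉, which makes
the round-trip property clean: the recovered δ′ never exceeds δ and the
relative gap is bounded by the ceiling slack (≈ 1−√(n/(n+1))), with exact
equality when the pre-ceiling sizes are integral. Ceilings are taken with a
10⁻⁹ slack so float artefacts (e.g. 63/0.9 = 70.000000000000014) do not round
up a size that is integral in exact arithmetic.

## Optimism and summaries

Per trial: discrepancy = δ_target − d_obs using the **final approved**
protocol version (never the first submitted one), relative discrepancy =
discrepancy/δ_target, overestimated ⇔ discrepancy > 0 strictly; exact ties
count as not overestimated and are reported separately, so the
over/underestimated counts partition the cohort with no third class.

Quantiles use the type-7 (linear interpolation, h = (n−1)p + 1) convention
throughout, implemented via `numpy.quantile(method="linear")` and checked in
the tests against an independent sort-and-interpolate oracle. The convention
is load-bearing: on the small per-phase samples summarised in the
modification analysis, other conventions give different quartiles. Display
rounding is two decimals, round-half-even; all comparisons are on unrounded
values.

Modification impact per phase (ethics review vs amendment) takes, per trial,
the standardised target at the earliest modified version ("before") and at
the latest ("after"), so a trial with several modifications contributes its
net change and intermediate oscillations collapse. Net changes are classified
by strict sign. The stratified summary groups per-trial optimism by any
cohort stratum; its discrepancy quantiles summarise per-trial differences,
which is not the same as differencing the target and observed medians (the
output carries this caveat).

Eligibility filtering assigns each excluded trial exactly one reason, checked
in order: no results, then insufficient information to standardise the
target, then achieved/target sample size strictly below the threshold
(default 0.4; a trial achieving exactly 0.4 of its target is included).

## Synthetic cohorts

The generator draws a true standardised effect δ_true per trial from a
log-normal distribution (default median 0.35, log-SD 0.4) and sets the
hypothesised target to δ_target = ω·δ_true. Optimism is multiplicative
because the relative discrepancy is then scale-free (1−1/ω in the noiseless
limit) and recoverable independently of the effect's magnitude. The default
ω = 1.4 is anchored to cohort medians of roughly 0.60 (target) against 0.43
(observed) reported for REC-approved trial cohorts; it is configuration, not
a claim.

Observation noise is placed directly on the standardised scale,
d_obs ~ N(δ_true, √(1/n₁ₐ+1/n₂ₐ)), then back-converted to the raw outcome
scale, so one noise model covers all outcome types and the sampling variance
is exact by construction. Outcome types default to 50% continuous, 35%
binary, 15% time-to-event; powers to 0.8/0.9 (70/30); attrition to 0/0.1/0.2
(50/35/15); 1:1 allocation. Reporting gaps default to the observed marginals
of protocol cohorts: α unreported in 8% of trials, sidedness in 40%, the raw
target difference in 12%, the variability in 18%. Protocols generated with a
masked α or sidedness carry the conventional values (0.05, two-sided), so
the standardisation defaults are correct for them by construction — the
situation in which such defaults survive a check against publications.
Masking the raw target exercises the back-calculated route, whose recovered
target is within ceiling slack of the truth. Modification probabilities
default to 0.14 (ethics review) and 0.20 (amendments) with multiplicative
log-normal perturbations (log-SD 0.15) of the target between versions.
Results are present by default (an analysable cohort has results by
construction); `missing_result_prob` generates the upstream situation where
trials lack results and are excluded.

A single root seed spawns one substream per trial, so enlarging a cohort
never reshuffles earlier trials, and a fixed config + seed reproduces the
cohort byte for byte.

What passing recovery tests show — and what they do not: the generator's
observed effects are unbiased around δ_true and its targets are exactly
ω·δ_true, so recovery checks the pipeline's algebra and dispatch, not the
realism of any particular cohort. Real protocol cohorts add features the
generator deliberately omits: publication time-lag selection (negative trials
publish later, so result-available cohorts under-represent them), correlated
strata, non-normal small-sample results, and calculation errors. Conclusions
about real cohorts should rest on the data model and pipeline, not on the
generator's defaults.

## Problem sizes

The test suite and acceptance script use 1,000-design inversion sweeps,
1,000-list quantile sweeps, and synthetic cohorts of 25–2,000 trials
(2,000 for the null-recovery and headline summaries; 400 per point for the
ω-monotonicity check across five seeds). These sizes put Monte-Carlo error
well inside the asserted bounds (the median of 2,000 null discrepancies has
standard error ≈ 0.005 against a ±0.02 band) while keeping any single test
file in seconds.

## The packaged fixture

`trialoptim/data/table4_modifications.csv` records 20 sample-size
modifications across 17 trials (7 during ethics review, 11 amendments across
10 trials), each with the standardised target before and after, the total
sample-size change, the reason, who induced it, and the trial's standardised
observed effect. `table4_cohort()` lifts it into full trial records: each
version is encoded as a continuous outcome with unit SD and raw difference
equal to the standardised target (so direct standardisation returns the
tabulated value exactly), with sample sizes derived from the design — a
synthetic carrier for tabulated standardised values, not raw trial data.

## Known limitations

- The back-calculation assumes the normal-approximation two-sample formula;
  protocols sized by exact binomial, log-rank event counts, or simulation
  will back-calculate to a slightly different implied δ. The consistency
  diagnostic surfaces large cases.
- Binary conversions use the logistic (odds-ratio) route even where a
  protocol reasoned in risk differences; the induced discrepancy metric is
  still internally consistent because targets and results convert the same
  way.
- The eligibility filter cannot detect non-two-arm designs from the data
  model alone; the model assumes its records already describe two-arm
  parallel superiority trials.
- No hypothesis testing or regression modelling of optimism predictors is
  provided; summaries are descriptive by design.
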