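# trialoptim

Optimism in clinical-trial sample-size calculations: standardise hypothesised
(target) and observed treatment effects onto a common scale, quantify how much
each trial overestimated the effect it was powered for, and trace targets
across protocol versions and research-ethics-committee (REC) review.

## The problem

A trial's sample size is driven by the effect its investigators hypothesise.
Hypothesised effects are frequently optimistic, which yields underpowered
trials, inconclusive results, and exaggerated estimates among the effects that
do reach significance. Quantifying that optimism across a cohort of trials
requires comparing targets and results across heterogeneous outcome types —
mean differences, odds ratios, hazard ratios — which this package does by
mapping everything onto the standardised (Cohen's *d*) scale.

For a two-arm parallel superiority trial with type-I error α (s-sided),
power 1−β and allocation ratio r = n₂/n₁, the normal-approximation sample-size
formula is

    n₁ = (z₁₋α/ₛ + z₁₋β)² (1 + 1/r) / δ²,   n₂ = r·n₁,

where δ is the standardised target difference. Inverting it gives the target
implied by a protocol that reports only design parameters and sample size:

    δ = (z₁₋α/ₛ + z₁₋β) · √(1/n₁ + 1/n₂).

Raw-scale targets convert directly: δ = Δ/SD for continuous outcomes, and
δ = |ln OR|·√3/π or |ln HR|·√3/π for binary and time-to-event outcomes (the
logistic-variance conversion). Observed results convert the same way, from
effect estimates, test statistics, or p-values with achieved sample sizes.
Per trial, optimism is

    discrepancy = δ_target (final approved protocol) − d_observed,

with the relative discrepancy = discrepancy / δ_target; a trial overestimated
its target iff the discrepancy is strictly positive. Cohort summaries are
medians with interquartile ranges under the type-7 quantile convention, with
no hypothesis testing.

The package provides:

- `trialoptim.model` / `trialoptim.cohort` — a typed cohort data model
  (protocol versions, REC comments, modifications, results), CSV/JSON
  readers and writers, completeness assessment, eligibility filtering;
- `trialoptim.standardise` — the standardisation core (back-calculation,
  forward sizing, ratio conversions, observed-effect dispatch);
- `trialoptim.optimism` — per-trial optimism, version trajectories,
  modification impact, stratified summaries;
- `trialoptim.synthetic` — a synthetic cohort generator with known ground
  truth (true effects, a multiplicative optimism factor ω, reporting
  missingness, noisy results) for parameter-recovery testing;
- `trialoptim.fixtures` — a packaged table of 17 trials whose sample-size
  calculations were modified during ethics review or amendments;
- a `trialoptim` command line (`simulate`, `standardise`, `analyse`,
  `report`, `fixtures`).

## Worked example

```python
from trialoptim import (
    DesignParameters, backcalculate_target_es, forward_sample_size,
    table4_cohort, modification_impact, compute_optimism,
)

# a design powered for half an SD needs 63 evaluable participants per arm
design = DesignParameters(alpha=0.05, sided="two", power=0.8,
                          outcome_type="continuous")
forward_sample_size(0.5, design)                      # (63, 63)

# and inverting 126 evaluable participants recovers the implied target
backcalculate_target_es(
    design.model_copy(update={"n_target_evaluable": 126})
).value                                               # 0.4992

# the packaged fixture: 17 trials that modified their calculation
cohort = table4_cohort()
ethics = modification_impact(cohort, "ethics_review")
(ethics.n_trials, round(ethics.before.median, 2),
 round(ethics.after.median, 2), ethics.n_decrease)    # (7, 0.81, 0.7, 2)

amend = modification_impact(cohort, "amendment")
(round(amend.before.median, 2), round(amend.after.median, 2),
 round(amend.after.q3, 2))                            # (0.51, 0.53, 0.66)

# per-trial optimism: amendment trial A1 targeted 0.42 but observed 0.03
opt = compute_optimism(next(t for t in cohort if t.trial_id == "A1"))
(round(opt.discrepancy, 2), round(opt.relative_discrepancy, 3),
 opt.overestimated)                                   # (0.39, 0.929, True)
```

Modifications during ethics review moved the median standardised target from
0.81 to 0.70 across the seven modified trials (a net decrease for only two of
them); amendment-phase modifications left the median essentially unchanged
(0.51 → 0.53). Trial A1's result fell far short of its target: 93% of the
hypothesised standardised effect never materialised.

The same analysis runs from the shell:

```sh
trialoptim simulate --out sim --n-trials 50 --seed 7
trialoptim report sim/cohort --outdir report
cat report/headline.txt
```

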