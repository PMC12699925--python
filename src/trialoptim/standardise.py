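"""Standardised (Cohen's-d scale) effect sizes for trial targets and results.

A two-arm superiority trial powered at 1−β with type-I error α (s-sided) to
detect a standardised difference δ needs, under the normal approximation,

    n1 = (z_{1−α/s} + z_{power})² · (1 + 1/r) / δ²,      n2 = r · n1,

with allocation ratio r = n2/n1.  Inverting this gives the *implied*
standardised target effect of a protocol that reports only α, power,
sidedness and sample size:

    δ = (z_{1−α/s} + z_{power}) · sqrt(1/n1 + 1/n2).

This back-calculated δ is a composite of the hypothesised raw effect and the
assumed variability, which is exactly what makes targets comparable across
outcome types.  Where the protocol states the raw components, the direct
forms are preferred: δ = Δ/SD for continuous outcomes, and |ln ratio|·√3/π
for odds or hazard ratios (the logistic-variance conversion, π²/3 being the
variance of the standard logistic distribution).

Observed results are mapped onto the same scale in a fixed
most-information-first priority; signs are positive when the observed
direction agrees with the hypothesised direction, negative on reversals.

Missing α defaults to 0.05 and missing sidedness to two-sided; every default
applied is recorded in ``assumptions_applied``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm, t as t_dist

from .model import DesignParameters, OutcomeResult, Sided

__all__ = [
    "SQRT3_OVER_PI",
    "InsufficientInformationError",
    "StandardisedEffect",
    "CriticalValues",
    "critical_values",
    "backcalculate_target_es",
    "forward_sample_size",
    "target_es_from_binary",
    "target_es_from_hazard",
    "standardise_target",
    "standardise_observed",
    "consistency_mismatch",
]

#: Scale factor mapping a log-odds (or log-hazard) ratio to Cohen's d.
SQRT3_OVER_PI = math.sqrt(3.0) / math.pi

#: Degrees of freedom above which a t statistic is treated as a z statistic.
T_AS_Z_DF = 30

#: Slack used when taking ceilings of float ratios, so that quantities that
#: are integral up to representation error (e.g. 63/0.9) do not round up.
_CEIL_EPS = 1e-9


def _ceil(x: float) -> int:
    return int(math.ceil(x - _CEIL_EPS))


class InsufficientInformationError(Exception):
    """Raised when no route to a standardised effect exists for a record.

    Mirrors the exclusion reason "insufficient information available from the
    protocol" used when assembling an analysable cohort.
    """


@dataclass(frozen=True)
class StandardisedEffect:
    """A dimensionless effect on the Cohen's-d scale.

    ``value`` is signed: positive in the direction favouring the trial's
    hypothesis.  Target effects are strictly positive (a superiority target
    of zero is invalid); observed effects may be zero or negative.
    ``diagnostic_backcalculated`` carries the back-calculated counterpart of
    a directly-computed target, for consistency checking against the
    protocol's own sample size.
    """

    value: float
    provenance: str
    assumptions_applied: tuple[str, ...] = ()
    diagnostic_backcalculated: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"standardised effect must be finite, got {self.value}")


@dataclass(frozen=True)
class CriticalValues:
    """Standard-normal quantiles entering the sample-size formula."""

    z_alpha: float
    z_beta: float
    assumptions_applied: tuple[str, ...] = ()

    @property
    def total(self) -> float:
        return self.z_alpha + self.z_beta


def critical_values(
    alpha: float | None, sided: Sided | None, power: float | None
) -> CriticalValues:
    """Critical values z_{1−α/s} and z_{power}, applying the standard defaults.

    Absent ``alpha`` defaults to 0.05 and absent ``sided`` to two-sided; each
    applied default is recorded in ``assumptions_applied``.  Power has no
    default: a protocol not stating its power cannot be back-calculated.
    """
    assumptions: list[str] = []
    if alpha is None:
        alpha = 0.05
        assumptions.append("alpha_defaulted")
    if sided is None:
        sided = "two"
        assumptions.append("sided_defaulted")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    if power is None:
        raise InsufficientInformationError("power is not reported")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie strictly in (0, 1), got {power}")
    s = 2.0 if sided == "two" else 1.0
    return CriticalValues(
        z_alpha=float(norm.ppf(1.0 - alpha / s)),
        z_beta=float(norm.ppf(power)),
        assumptions_applied=tuple(assumptions),
    )


def _per_arm_evaluable(d: DesignParameters, assumptions: list[str]) -> tuple[int, int]:
    """Evaluable per-arm sizes from whichever sample-size field is available.

    Prefers the stated evaluable total; otherwise deflates the enrolment
    target by the attrition rate (evaluable = floor(enrolment · (1−a))),
    recording the assumption.
    """
    if d.n_target_evaluable is not None:
        total = d.n_target_evaluable
    elif d.n_target_total is not None:
        total = d.n_target_total
        if d.attrition_rate:
            total = int(math.floor(total * (1.0 - d.attrition_rate) + _CEIL_EPS))
            assumptions.append("attrition_deflated_enrolment_total")
    else:
        raise InsufficientInformationError(
            "no target sample size from which to derive per-arm sizes"
        )
    r = d.allocation_ratio
    # largest n1 whose ratio-consistent pair (n1, ceil(r*n1)) fits the total;
    # this exactly inverts the forward construction and degrades gracefully
    # (floor split) on totals that did not come from it
    n1 = max(1, int(total / (1.0 + r)) - 2)
    while n1 + _ceil(r * (n1 + 1)) + 1 <= total:
        n1 += 1
    n2 = total - n1
    return n1, n2


def backcalculate_target_es(d: DesignParameters) -> StandardisedEffect:
    """Implied standardised target effect from α, sidedness, power and sample size.

    δ = (z_alpha + z_beta) · sqrt(1/n1 + 1/n2).  This inverts the two-sample
    normal-approximation sample-size formula and is applicable to any outcome
    type, because the standardised target is a composite of the hypothesised
    effect and its variability.
    """
    cv = critical_values(d.alpha, d.sided, d.power)
    assumptions = list(cv.assumptions_applied)
    n1, n2 = _per_arm_evaluable(d, assumptions)
    if n1 < 2 or n2 < 2:
        raise ValueError(f"per-arm sizes must be >= 2, got n1={n1}, n2={n2}")
    delta = cv.total * math.sqrt(1.0 / n1 + 1.0 / n2)
    return StandardisedEffect(delta, "back_calculated", tuple(assumptions))


def forward_sample_size(
    delta: float, d: DesignParameters, inflate_attrition: bool = False
) -> tuple[int, int]:
    """Per-arm sample sizes needed to detect standardised difference ``delta``.

    n1 = ceil((z_alpha + z_beta)² · (1 + 1/r) / δ²), n2 = ceil(r · n1).  With
    ``inflate_attrition`` the evaluable sizes are inflated to enrolment
    targets by dividing by (1 − attrition_rate).
    """
    if not delta > 0.0:
        raise ValueError(f"delta must be > 0, got {delta}")
    cv = critical_values(d.alpha, d.sided, d.power)
    r = d.allocation_ratio
    n1 = _ceil(cv.total**2 * (1.0 + 1.0 / r) / delta**2)
    n2 = _ceil(r * n1)
    if inflate_attrition and d.attrition_rate:
        n1 = _ceil(n1 / (1.0 - d.attrition_rate))
        n2 = _ceil(n2 / (1.0 - d.attrition_rate))
    return n1, n2


def _d_from_log_ratio(log_ratio: float) -> float:
    return abs(log_ratio) * SQRT3_OVER_PI


def target_es_from_binary(p_control: float, p_treat: float) -> StandardisedEffect:
    """Standardised effect implied by control and treatment event rates.

    δ = |ln OR| · √3/π with OR the treatment-vs-control odds ratio.  Symmetric
    under swapping the arms (OR and 1/OR map to the same δ).
    """
    for name, p in (("p_control", p_control), ("p_treat", p_treat)):
        if not 0.0 < p < 1.0:
            raise ValueError(
                f"{name} must lie strictly in (0, 1), got {p}; supply a "
                "continuity-corrected rate upstream for boundary values"
            )
    odds_ratio = (p_treat / (1.0 - p_treat)) / (p_control / (1.0 - p_control))
    return StandardisedEffect(_d_from_log_ratio(math.log(odds_ratio)), "converted_log_odds")


def target_es_from_hazard(hr: float) -> StandardisedEffect:
    """Standardised effect implied by a hazard ratio: δ = |ln HR| · √3/π."""
    if not hr > 0.0:
        raise ValueError(f"hazard ratio must be > 0, got {hr}")
    return StandardisedEffect(_d_from_log_ratio(math.log(hr)), "converted_log_hazard")


def _hypothesised_log_sign(d: DesignParameters) -> int | None:
    """Sign of the hypothesised log-ratio, when derivable from the target."""
    if d.outcome_type == "binary":
        if d.target_difference is not None and d.variability_or_control_rate is not None:
            p_c = d.variability_or_control_rate
            p_t = p_c + d.target_difference
            if 0.0 < p_c < 1.0 and 0.0 < p_t < 1.0 and p_t != p_c:
                odds_ratio = (p_t / (1.0 - p_t)) / (p_c / (1.0 - p_c))
                return 1 if math.log(odds_ratio) > 0 else -1
    elif d.outcome_type == "time_to_event":
        if d.target_difference is not None and d.target_difference > 0 and d.target_difference != 1.0:
            return 1 if math.log(d.target_difference) > 0 else -1
    return None


def standardise_target(d: DesignParameters) -> StandardisedEffect:
    """Standardised target effect of one protocol version.

    Dispatch: a continuous target with a stated difference and SD is the
    direct ratio Δ/SD; a binary target with both event rates converts via the
    log odds ratio; a time-to-event target with a hazard ratio converts via
    the log hazard ratio; anything else is back-calculated from α, sidedness,
    power and sample size.  When a direct value is computable, the
    back-calculated counterpart (if also computable) is retained in
    ``diagnostic_backcalculated`` so that gross mismatches — candidate
    calculation errors — can be flagged.
    """
    direct: float | None = None
    provenance = "direct"
    if d.outcome_type == "continuous":
        if d.target_difference is not None and d.variability_or_control_rate is not None:
            if d.variability_or_control_rate <= 0:
                raise ValueError("SD must be > 0")
            direct = abs(d.target_difference) / d.variability_or_control_rate
    elif d.outcome_type == "binary":
        if d.target_difference is not None and d.variability_or_control_rate is not None:
            p_c = d.variability_or_control_rate
            direct = target_es_from_binary(p_c, p_c + d.target_difference).value
            provenance = "converted_log_odds"
    elif d.outcome_type == "time_to_event":
        if d.target_difference is not None:
            direct = target_es_from_hazard(d.target_difference).value
            provenance = "converted_log_hazard"

    if direct is not None:
        if direct <= 0.0:
            raise ValueError(
                "a superiority target difference of zero is invalid: the "
                "standardised target effect must be strictly positive"
            )
        try:
            back = backcalculate_target_es(d).value
        except (InsufficientInformationError, ValueError):
            back = None
        return StandardisedEffect(direct, provenance, (), back)
    return backcalculate_target_es(d)


def consistency_mismatch(es: StandardisedEffect, tolerance: float = 0.2) -> bool:
    """Flag a direct target whose back-calculated counterpart disagrees by more
    than ``tolerance`` — a candidate "potential calculation error"."""
    if es.diagnostic_backcalculated is None:
        return False
    return abs(es.value - es.diagnostic_backcalculated) > tolerance


def standardise_observed(r: OutcomeResult, d: DesignParameters) -> StandardisedEffect:
    """Standardised observed effect of the primary-outcome result.

    Dispatch, in fixed most-information-first priority:

    1. continuous effect estimate with a pooled SD: d = Δ̂ / SD;
    2. odds/hazard ratio estimate: d = sign · |ln est| · √3/π;
    3. test statistic z (or an implied z = Δ̂/SE, or a t with df ≥ 30) with
       achieved per-arm sizes: d = z · sqrt(1/n1 + 1/n2); a t with df < 30 is
       first converted to a p-value through the t CDF and routed as (4);
    4. p-value with achieved per-arm sizes: z = Φ⁻¹(1 − p/s), signed by the
       reported direction, then as (3).

    The sign is positive iff the observed direction matches the hypothesised
    direction; when no direction information exists the effect is assumed to
    run in the hypothesised direction and the assumption is recorded.
    """
    assumptions: list[str] = []

    def _hyp_dir_continuous() -> int:
        if d.target_difference is not None and d.target_difference != 0:
            return 1 if d.target_difference > 0 else -1
        assumptions.append("direction_assumed_positive")
        return 1

    def _ratio_sign(log_est: float) -> int:
        hyp = _hypothesised_log_sign(d)
        if hyp is not None:
            return 1 if (log_est > 0) == (hyp > 0) or log_est == 0 else -1
        if r.direction_matches_hypothesis is not None:
            return 1 if r.direction_matches_hypothesis else -1
        assumptions.append("direction_assumed_matching")
        return 1

    # (1) continuous means with pooled SD
    if (
        d.outcome_type == "continuous"
        and r.effect_estimate is not None
        and r.sd_pooled is not None
    ):
        if r.sd_pooled <= 0:
            raise ValueError("pooled SD must be > 0")
        value = (r.effect_estimate / r.sd_pooled) * _hyp_dir_continuous()
        return StandardisedEffect(value, "direct", tuple(assumptions))

    # (2) ratio estimate on the log-odds / log-hazard scale
    if d.outcome_type in ("binary", "time_to_event") and r.effect_estimate is not None:
        if r.effect_estimate <= 0:
            raise ValueError(f"ratio estimate must be > 0, got {r.effect_estimate}")
        log_est = math.log(r.effect_estimate)
        value = _ratio_sign(log_est) * _d_from_log_ratio(log_est)
        provenance = (
            "converted_log_odds" if d.outcome_type == "binary" else "converted_log_hazard"
        )
        return StandardisedEffect(value, provenance, tuple(assumptions))

    n = r.n_achieved_per_arm

    # (3) test statistic with achieved sample sizes
    z: float | None = None
    if r.test_statistic is not None:
        df = r.test_statistic_df
        if df is not None and df < T_AS_Z_DF:
            # small-sample t: convert through the t CDF and route via the p-value
            sided = d.sided
            if sided is None:
                sided = "two"
                assumptions.append("sided_defaulted")
            s = 2.0 if sided == "two" else 1.0
            p = s * (1.0 - float(t_dist.cdf(abs(r.test_statistic), df)))
            return _from_p(
                min(p, 1.0), r.test_statistic >= 0, sided, n, assumptions,
                provenance="from_p_value",
            )
        z = r.test_statistic
    elif (
        d.outcome_type == "continuous"
        and r.effect_estimate is not None
        and r.se is not None
    ):
        z = (r.effect_estimate / r.se) * _hyp_dir_continuous()
    if z is not None:
        if n is None:
            raise InsufficientInformationError(
                "achieved per-arm sizes are required to standardise a test statistic"
            )
        value = z * math.sqrt(1.0 / n[0] + 1.0 / n[1])
        return StandardisedEffect(value, "from_test_statistic", tuple(assumptions))

    # (4) p-value with achieved sample sizes
    if r.p_value is not None:
        if n is None:
            raise InsufficientInformationError(
                "achieved per-arm sizes are required to standardise a p-value"
            )
        sided = d.sided
        if sided is None:
            sided = "two"
            assumptions.append("sided_defaulted")
        matches = r.direction_matches_hypothesis
        if matches is None:
            matches = True
            assumptions.append("direction_assumed_matching")
        return _from_p(r.p_value, matches, sided, n, assumptions)

    raise InsufficientInformationError(
        "no route to a standardised observed effect from the reported summaries"
    )


def _from_p(
    p: float,
    matches_hypothesis: bool,
    sided: Sided,
    n: tuple[int, int] | None,
    assumptions: list[str],
    provenance: str = "from_p_value",
) -> StandardisedEffect:
    if n is None:
        raise InsufficientInformationError(
            "achieved per-arm sizes are required to standardise a p-value"
        )
    s = 2.0 if sided == "two" else 1.0
    z = float(norm.ppf(1.0 - p / s))
    sign = 1.0 if matches_hypothesis else -1.0
    value = sign * z * math.sqrt(1.0 / n[0] + 1.0 / n[1])
    return StandardisedEffect(value, provenance, tuple(assumptions))
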