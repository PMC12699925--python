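"""Per-trial optimism, version trajectories, and stratified summaries.

Optimism of a trial's sample-size calculation is the discrepancy between the
standardised target effect of the *final approved* protocol and the
standardised observed effect of the primary outcome:

    discrepancy = δ_target − d_obs,
    relative discrepancy = discrepancy / δ_target.

A trial overestimated its target iff the discrepancy is strictly positive;
ties count as not overestimated and are reported separately.  Cohort
summaries are medians with interquartile ranges under the type-7
(linear-interpolation) quantile convention — the convention matters, because
other conventions give different quartiles on the small per-phase samples
summarised here.  No hypothesis testing is performed anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .model import STRATUM_KEYS, ModificationPhase, TrialRecord
from .standardise import (
    InsufficientInformationError,
    StandardisedEffect,
    standardise_observed,
    standardise_target,
)

__all__ = [
    "OptimismResult",
    "Trajectory",
    "QuantileSummary",
    "compute_optimism",
    "compute_optimism_cohort",
    "quantile_summary",
    "summarise",
    "trajectory",
    "ModificationImpact",
    "modification_impact",
    "stratified_optimism",
    "OverestimationSummary",
    "overestimation_proportion",
    "round_display",
]


def round_display(x: float, ndigits: int = 2) -> float:
    """Display rounding: two decimals, round-half-even.  Internal comparisons
    always use unrounded values."""
    return round(float(x), ndigits)


@dataclass(frozen=True)
class OptimismResult:
    """Optimism of one trial's sample-size calculation."""

    trial_id: str
    target_es: StandardisedEffect
    observed_es: StandardisedEffect
    discrepancy: float
    relative_discrepancy: float
    overestimated: bool


@dataclass(frozen=True)
class Trajectory:
    """Standardised target effect across protocol versions, ending at the
    observed effect (label ``"observed"``)."""

    trial_id: str
    points: tuple[tuple[str, float], ...]


def compute_optimism(t: TrialRecord) -> OptimismResult:
    """Discrepancy between the final approved target and the observed effect.

    Uses the FINAL approved protocol version (never the first submitted one).
    Raises :class:`InsufficientInformationError` when either side cannot be
    standardised, so callers can flag rather than silently drop the trial.
    """
    if t.result is None:
        raise InsufficientInformationError(
            f"trial {t.trial_id!r}: no primary-outcome result"
        )
    target = standardise_target(t.final_approved)
    observed = standardise_observed(t.result, t.final_approved)
    discrepancy = target.value - observed.value
    return OptimismResult(
        trial_id=t.trial_id,
        target_es=target,
        observed_es=observed,
        discrepancy=discrepancy,
        relative_discrepancy=discrepancy / target.value,
        overestimated=discrepancy > 0.0,
    )


def compute_optimism_cohort(
    cohort: Sequence[TrialRecord],
) -> tuple[list[OptimismResult], list[tuple[str, str]]]:
    """Optimism for every standardisable trial; failures returned as
    (trial_id, message) pairs instead of aborting the run."""
    results: list[OptimismResult] = []
    failures: list[tuple[str, str]] = []
    for t in cohort:
        try:
            results.append(compute_optimism(t))
        except (InsufficientInformationError, ValueError) as exc:
            failures.append((t.trial_id, str(exc)))
    return results, failures


def quantile_summary(
    values: Sequence[float], probs: Sequence[float] | float
) -> np.ndarray:
    """Sample quantiles under the type-7 linear-interpolation convention:
    h = (n−1)p + 1 on the order statistics.  Errors on an empty input."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarise an empty list of values")
    return np.quantile(arr, np.asarray(probs, dtype=float), method="linear")


@dataclass(frozen=True)
class QuantileSummary:
    """Median with interquartile range, plus the sample size."""

    n: int
    median: float
    q1: float
    q3: float


def summarise(values: Sequence[float]) -> QuantileSummary:
    q1, med, q3 = quantile_summary(values, (0.25, 0.5, 0.75))
    return QuantileSummary(n=len(values), median=float(med), q1=float(q1), q3=float(q3))


def trajectory(t: TrialRecord) -> Trajectory:
    """Per-version standardised target effects, terminated by the observed effect."""
    points: list[tuple[str, float]] = []
    for v in t.versions:
        label = v.version_label or f"version_{v.version_index}"
        points.append((label, standardise_target(v).value))
    if t.result is not None:
        points.append(("observed", standardise_observed(t.result, t.final_approved).value))
    return Trajectory(t.trial_id, tuple(points))


@dataclass(frozen=True)
class ModificationImpact:
    """Effect of sample-size modifications in one phase on the target effect.

    ``before`` summarises the standardised target at the earliest modified
    version, ``after`` at the latest; a trial with several modifications in
    the phase contributes its net change, so intermediate oscillations
    collapse to a single before→after pair.
    """

    phase: ModificationPhase
    n_trials: int
    before: Optional[QuantileSummary]
    after: Optional[QuantileSummary]
    n_decrease: int
    n_increase: int
    n_no_change: int
    per_trial: pd.DataFrame


def modification_impact(
    cohort: Sequence[TrialRecord], phase: ModificationPhase
) -> ModificationImpact:
    """Summarise target-effect change across trials modified during ``phase``.

    Net change per trial is classified by the strict sign of after − before.
    An empty phase yields an empty summary (no error).
    """
    if phase not in ("ethics_review", "amendment"):
        raise ValueError(f"unknown phase {phase!r}")
    rows = []
    for t in cohort:
        mods = [m for m in t.modifications if m.phase == phase]
        if not mods:
            continue
        first_from = min(m.from_version for m in mods)
        last_to = max(m.to_version for m in mods)
        before = standardise_target(t.version_at(first_from)).value
        after = standardise_target(t.version_at(last_to)).value
        rows.append(
            {
                "trial_id": t.trial_id,
                "before": before,
                "after": after,
                "change": after - before,
            }
        )
    per_trial = pd.DataFrame(rows, columns=["trial_id", "before", "after", "change"])
    if per_trial.empty:
        return ModificationImpact(phase, 0, None, None, 0, 0, 0, per_trial)
    return ModificationImpact(
        phase=phase,
        n_trials=len(per_trial),
        before=summarise(per_trial["before"].tolist()),
        after=summarise(per_trial["after"].tolist()),
        n_decrease=int((per_trial["change"] < 0).sum()),
        n_increase=int((per_trial["change"] > 0).sum()),
        n_no_change=int((per_trial["change"] == 0).sum()),
        per_trial=per_trial,
    )


def _stratum_extractors() -> dict[str, Callable[[TrialRecord], str]]:
    def attr(name: str) -> Callable[[TrialRecord], str]:
        return lambda t: str(getattr(t, name)) if getattr(t, name) is not None else "unknown"

    return {
        "all": lambda t: "all",
        "sponsor": attr("sponsor"),
        "centres": attr("centres"),
        "medical_field": attr("medical_field"),
        "intervention_type": attr("intervention_type"),
        "phase": attr("phase"),
        "comparator": attr("comparator"),
        "masking": attr("masking"),
        "outcome_type": lambda t: t.final_approved.outcome_type,
        "elicitation_method": lambda t: t.final_approved.elicitation_method,
        "significant": lambda t: (
            "unknown"
            if t.result is None or t.result.significant is None
            else ("significant" if t.result.significant else "non_significant")
        ),
        "rec_comment": lambda t: "with_comment" if t.comments else "without_comment",
        "modified_ethics_review": lambda t: (
            "modified" if t.has_modification("ethics_review") else "not_modified"
        ),
        "modified_amendment": lambda t: (
            "modified" if t.has_modification("amendment") else "not_modified"
        ),
    }


def stratified_optimism(
    results: Sequence[OptimismResult],
    records: Sequence[TrialRecord],
    stratum_key: str,
) -> pd.DataFrame:
    """Median/IQR of target ES, observed ES and discrepancy per stratum.

    The discrepancy row summarises the per-trial differences: the median of
    differences is not the difference of medians, so over/underestimation can
    be present even where the target and observed medians look similar (the
    DataFrame carries this caveat in ``attrs["note"]``).
    """
    extractors = _stratum_extractors()
    if stratum_key not in extractors:
        raise KeyError(
            f"unknown stratum key {stratum_key!r}; known keys: {sorted(STRATUM_KEYS)}"
        )
    by_id = {t.trial_id: t for t in records}
    groups: dict[str, list[OptimismResult]] = {}
    for r in results:
        label = extractors[stratum_key](by_id[r.trial_id])
        groups.setdefault(label, []).append(r)

    rows = []
    for label in sorted(groups):
        rs = groups[label]
        tgt = summarise([r.target_es.value for r in rs])
        obs = summarise([r.observed_es.value for r in rs])
        dis = summarise([r.discrepancy for r in rs])
        rows.append(
            {
                "stratum": label,
                "n": len(rs),
                "target_median": tgt.median,
                "target_q1": tgt.q1,
                "target_q3": tgt.q3,
                "observed_median": obs.median,
                "observed_q1": obs.q1,
                "observed_q3": obs.q3,
                "discrepancy_median": dis.median,
                "discrepancy_q1": dis.q1,
                "discrepancy_q3": dis.q3,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["note"] = (
        "discrepancy quantiles summarise per-trial differences; the median of "
        "differences need not equal the difference of the target and observed medians"
    )
    return df


@dataclass(frozen=True)
class OverestimationSummary:
    n_total: int
    n_overestimated: int
    n_underestimated: int
    n_ties: int
    proportion: float


def overestimation_proportion(results: Sequence[OptimismResult]) -> OverestimationSummary:
    """Fraction of trials with strictly positive discrepancy; ties (exactly
    zero) count as not overestimated and are reported separately."""
    if not results:
        raise ValueError("cannot summarise an empty list of optimism results")
    n_over = sum(1 for r in results if r.discrepancy > 0)
    n_tie = sum(1 for r in results if r.discrepancy == 0)
    n = len(results)
    return OverestimationSummary(
        n_total=n,
        n_overestimated=n_over,
        n_underestimated=n - n_over - n_tie,
        n_ties=n_tie,
        proportion=n_over / n,
    )
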