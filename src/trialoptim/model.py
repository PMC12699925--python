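"""Typed representation of a clinical-trial cohort across protocol versions.

The central object is :class:`TrialRecord`: one two-arm parallel superiority
trial with an ordered list of protocol versions (each carrying the design
parameters its sample-size calculation consumed), the comments raised by the
research ethics committee (REC) during review, the sample-size modifications
made during ethics review or later amendments, and the primary-outcome result.

Absent fields always carry an explicit ``None`` marker; nothing is silently
defaulted at this layer.  Defaults (e.g. alpha = 0.05, two-sided) are applied
only by the standardisation layer, which records every assumption it makes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

OutcomeType = Literal["continuous", "binary", "time_to_event"]
Sided = Literal["one", "two"]
ElicitationMethod = Literal[
    "literature_review",
    "pilot_study",
    "opinion_seeking",
    "standardised_es",
    "mixed",
    "other",
    "not_mentioned",
]
CommentCategory = Literal[
    "absence_of_calculation",
    "unclear_missing_parameters",
    "parameter_justification_request",
    "calculation_error",
    "other",
]
ModificationPhase = Literal["ethics_review", "amendment"]
InducedBy = Literal["REC", "investigator"]
ResultSource = Literal["publication", "results_report", "trial_record"]

#: Stratification keys understood by the analysis layer.
STRATUM_KEYS = (
    "all",
    "sponsor",
    "centres",
    "medical_field",
    "intervention_type",
    "phase",
    "comparator",
    "masking",
    "outcome_type",
    "elicitation_method",
    "significant",
    "rec_comment",
    "modified_ethics_review",
    "modified_amendment",
)


class DesignParameters(BaseModel):
    """Everything a two-arm sample-size calculation consumes, for one protocol version.

    ``n_target_total`` is the enrolment target (after any attrition inflation);
    ``n_target_evaluable`` is the analytic target before attrition, when the
    protocol distinguishes the two.  ``target_difference`` is on the raw
    outcome scale: a mean difference for continuous outcomes, a risk
    difference against ``variability_or_control_rate`` (the control event
    rate) for binary outcomes, and a hazard ratio for time-to-event outcomes.
    """

    model_config = ConfigDict(extra="forbid")

    version_index: int = 1
    version_label: Optional[str] = None
    alpha: Optional[float] = None
    sided: Optional[Sided] = None
    power: Optional[float] = None
    allocation_ratio: float = 1.0
    n_target_total: Optional[int] = None
    n_target_evaluable: Optional[int] = None
    attrition_rate: Optional[float] = None
    outcome_type: OutcomeType = "continuous"
    target_difference: Optional[float] = None
    variability_or_control_rate: Optional[float] = None
    elicitation_method: ElicitationMethod = "not_mentioned"

    @field_validator("alpha")
    @classmethod
    def _alpha_open_unit(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 < v < 1.0:
            raise ValueError(f"alpha must lie strictly in (0, 1), got {v}")
        return v

    @field_validator("power")
    @classmethod
    def _power_open_unit(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 < v < 1.0:
            raise ValueError(f"power must lie strictly in (0, 1), got {v}")
        return v

    @field_validator("allocation_ratio")
    @classmethod
    def _ratio_positive(cls, v: float) -> float:
        if not v > 0.0:
            raise ValueError(f"allocation_ratio must be > 0, got {v}")
        return v

    @field_validator("n_target_total", "n_target_evaluable")
    @classmethod
    def _n_at_least_two(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 2:
            raise ValueError(f"sample-size targets must be >= 2, got {v}")
        return v

    @field_validator("attrition_rate")
    @classmethod
    def _attrition_in_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 <= v < 1.0:
            raise ValueError(f"attrition_rate must lie in [0, 1), got {v}")
        return v

    @property
    def calculation_absent(self) -> bool:
        """True when no component of a sample-size calculation is recorded at all."""
        return all(
            getattr(self, f) is None
            for f in (
                "alpha",
                "power",
                "sided",
                "target_difference",
                "variability_or_control_rate",
                "n_target_total",
                "n_target_evaluable",
            )
        )


class RECComment(BaseModel):
    """One REC comment on the sample-size calculation, in the five-category taxonomy."""

    model_config = ConfigDict(extra="forbid")

    category: CommentCategory
    text_note: str = ""
    version_raised: int = 1


class Modification(BaseModel):
    """One modification of the sample-size calculation between adjacent protocol versions."""

    model_config = ConfigDict(extra="forbid")

    phase: ModificationPhase
    from_version: int
    to_version: int
    reason: str = ""
    induced_by: InducedBy = "investigator"
    sample_size_change_fraction: Optional[float] = None

    @model_validator(mode="after")
    def _adjacent_versions(self) -> "Modification":
        if self.to_version != self.from_version + 1:
            raise ValueError(
                f"to_version must equal from_version + 1, got {self.from_version} -> {self.to_version}"
            )
        return self


class OutcomeResult(BaseModel):
    """Primary-outcome result of a trial, in whichever summary form was reported.

    The standardisation layer consumes whatever combination is present, in a
    fixed most-information-first priority: raw effect with a pooled SD
    (continuous) or a ratio estimate (binary / time-to-event), then a test
    statistic with achieved sample sizes, then a p-value with achieved sample
    sizes.  At least one such route must be available.
    """

    model_config = ConfigDict(extra="forbid")

    effect_estimate: Optional[float] = None
    se: Optional[float] = None
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    sd_pooled: Optional[float] = None
    test_statistic: Optional[float] = None
    test_statistic_df: Optional[int] = None
    p_value: Optional[float] = None
    n_achieved_per_arm: Optional[tuple[int, int]] = None
    significant: Optional[bool] = None
    direction_matches_hypothesis: Optional[bool] = None
    source: Optional[ResultSource] = None

    @field_validator("p_value")
    @classmethod
    def _p_in_range(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not 0.0 < v <= 1.0:
            raise ValueError(f"p_value must lie in (0, 1], got {v}")
        return v

    @field_validator("n_achieved_per_arm")
    @classmethod
    def _n_positive(cls, v: Optional[tuple[int, int]]) -> Optional[tuple[int, int]]:
        if v is not None and (v[0] < 1 or v[1] < 1):
            raise ValueError(f"achieved per-arm sizes must be positive, got {v}")
        return v

    @property
    def has_dispersion(self) -> bool:
        return (
            self.se is not None
            or self.sd_pooled is not None
            or (self.ci_lower is not None and self.ci_upper is not None)
        )

    @model_validator(mode="after")
    def _some_route_available(self) -> "OutcomeResult":
        has_n = self.n_achieved_per_arm is not None
        routes = (
            (self.effect_estimate is not None and self.has_dispersion),
            (self.test_statistic is not None and has_n),
            (self.p_value is not None and has_n),
        )
        if not any(routes):
            raise ValueError(
                "result must provide at least one of: effect estimate with a dispersion "
                "measure (SE, CI or pooled SD); test statistic with achieved sample sizes; "
                "p-value with achieved sample sizes"
            )
        return self

    @property
    def n_achieved_total(self) -> Optional[int]:
        if self.n_achieved_per_arm is None:
            return None
        return self.n_achieved_per_arm[0] + self.n_achieved_per_arm[1]


class TrialRecord(BaseModel):
    """One trial: ordered protocol versions, REC comments, modifications, result, strata."""

    model_config = ConfigDict(extra="forbid")

    trial_id: str
    sponsor: Optional[Literal["investigator", "industry"]] = None
    centres: Optional[Literal["single_centre", "multicentre"]] = None
    medical_field: Optional[
        Literal[
            "internal_medicine",
            "oncology",
            "neurology_neurosurgery",
            "psychology_psychiatry",
            "other",
        ]
    ] = None
    intervention_type: Optional[
        Literal["drug", "device", "behavioural_digital", "other"]
    ] = None
    phase: Optional[Literal["1", "2", "3", "4", "other", "not_applicable"]] = None
    comparator: Optional[Literal["active", "placebo", "no_intervention"]] = None
    masking: Optional[Literal["open", "blinded"]] = None
    versions: list[DesignParameters]
    comments: list[RECComment] = []
    modifications: list[Modification] = []
    result: Optional[OutcomeResult] = None

    @field_validator("versions")
    @classmethod
    def _versions_ordered(cls, v: list[DesignParameters]) -> list[DesignParameters]:
        if not v:
            raise ValueError("versions must be non-empty")
        idx = [d.version_index for d in v]
        if idx != sorted(idx) or len(set(idx)) != len(idx):
            raise ValueError(f"version indices must be strictly increasing, got {idx}")
        return v

    @model_validator(mode="after")
    def _ethics_before_amendments(self) -> "TrialRecord":
        ethics_to = [m.to_version for m in self.modifications if m.phase == "ethics_review"]
        amend_from = [m.from_version for m in self.modifications if m.phase == "amendment"]
        if ethics_to and amend_from and max(ethics_to) > min(amend_from):
            raise ValueError(
                "ethics-review modifications must precede amendment modifications"
            )
        return self

    # -- derived version positions (labels are free text; positions are structural)

    @property
    def first_submitted(self) -> DesignParameters:
        return self.versions[0]

    @property
    def final_approved(self) -> DesignParameters:
        return self.versions[-1]

    @property
    def first_approved(self) -> DesignParameters:
        """Version in force after ethics review: the target of the last
        ethics-review modification, or the first submitted version if the
        calculation was not modified during review."""
        ethics_to = [m.to_version for m in self.modifications if m.phase == "ethics_review"]
        if not ethics_to:
            return self.versions[0]
        return self.version_at(max(ethics_to))

    def version_at(self, index: int) -> DesignParameters:
        for d in self.versions:
            if d.version_index == index:
                return d
        raise KeyError(f"trial {self.trial_id}: no protocol version with index {index}")

    def has_modification(self, phase: ModificationPhase) -> bool:
        return any(m.phase == phase for m in self.modifications)


# ---------------------------------------------------------------------------
# Completeness assessment


@dataclass(frozen=True)
class CompletenessReport:
    """Whether a sample-size calculation is reported completely enough to redo it."""

    complete: bool
    missing: tuple[str, ...] = ()


def assess_completeness(d: DesignParameters) -> CompletenessReport:
    """Assess whether every component needed to recalculate the sample size is reported.

    A calculation is complete when the type I error probability, power,
    hypothesis-test side, target difference, variability (or control event
    rate, where the outcome type requires one) and the resulting sample size
    are all present.  A protocol reporting none of these components at all is
    flagged with the single missing component ``"calculation"``.
    """
    if d.calculation_absent:
        return CompletenessReport(False, ("calculation",))
    missing: list[str] = []
    if d.alpha is None:
        missing.append("alpha")
    if d.power is None:
        missing.append("power")
    if d.sided is None:
        missing.append("hypothesis_test_side")
    if d.target_difference is None:
        missing.append("target_difference")
    # a hazard-ratio target is already a complete effect specification; continuous
    # and binary targets additionally need an SD / control event rate
    if d.outcome_type != "time_to_event" and d.variability_or_control_rate is None:
        missing.append("variability_or_event_rate")
    if d.n_target_total is None and d.n_target_evaluable is None:
        missing.append("sample_size")
    return CompletenessReport(not missing, tuple(missing))
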