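"""The standardisation core: critical values, back-calculation, conversions,
observed-effect dispatch, and their invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from trialoptim import (
    DesignParameters,
    InsufficientInformationError,
    OutcomeResult,
    backcalculate_target_es,
    consistency_mismatch,
    critical_values,
    forward_sample_size,
    standardise_observed,
    standardise_target,
    target_es_from_binary,
    target_es_from_hazard,
)
from trialoptim.standardise import SQRT3_OVER_PI


def _design(**kw):
    base = dict(alpha=0.05, sided="two", power=0.8, outcome_type="continuous")
    base.update(kw)
    return DesignParameters(**base)


class TestCriticalValues:
    @pytest.mark.parametrize(
        "alpha,sided,power,z_alpha,z_beta",
        [
            (0.05, "two", 0.80, 1.95996, 0.84162),
            (0.05, "one", 0.80, 1.64485, 0.84162),
            (0.5, "two", 0.5, 0.67449, 0.0),
        ],
    )
    def test_standard_normal_quantiles(self, alpha, sided, power, z_alpha, z_beta):
        cv = critical_values(alpha, sided, power)
        assert cv.z_alpha == pytest.approx(z_alpha, abs=1e-5)
        assert cv.z_beta == pytest.approx(z_beta, abs=1e-5)

    def test_defaults_applied_and_recorded(self):
        cv = critical_values(None, None, 0.8)
        assert cv.assumptions_applied == ("alpha_defaulted", "sided_defaulted")
        assert cv.z_alpha == pytest.approx(norm.ppf(0.975))

    def test_alpha_domain_error(self):
        with pytest.raises(ValueError, match="alpha"):
            critical_values(1.2, "two", 0.8)

    def test_missing_power_is_insufficient_information(self):
        with pytest.raises(InsufficientInformationError):
            critical_values(0.05, "two", None)


class TestBackCalculation:
    def test_two_sided_63_per_arm(self):
        d = _design(n_target_evaluable=126)
        es = backcalculate_target_es(d)
        assert es.value == pytest.approx(2.80158 * math.sqrt(2 / 63), abs=1e-4)
        assert es.value == pytest.approx(0.4992, abs=5e-4)
        assert es.provenance == "back_calculated"

    def test_one_sided_50_per_arm(self):
        d = _design(sided="one", n_target_evaluable=100)
        assert backcalculate_target_es(d).value == pytest.approx(0.4973, abs=5e-4)

    def test_strictly_decreasing_in_n(self):
        values = [
            backcalculate_target_es(_design(n_target_evaluable=n)).value
            for n in (20, 50, 100, 400, 2000, 20000)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 0.1  # delta -> 0 as n grows

    def test_strictly_increasing_in_power_and_decreasing_in_alpha(self):
        lo = backcalculate_target_es(_design(power=0.7, n_target_evaluable=100)).value
        hi = backcalculate_target_es(_design(power=0.9, n_target_evaluable=100)).value
        assert hi > lo
        tight = backcalculate_target_es(_design(alpha=0.01, n_target_evaluable=100)).value
        loose = backcalculate_target_es(_design(alpha=0.10, n_target_evaluable=100)).value
        assert tight > loose

    def test_attrition_deflates_enrolment_total(self):
        # enrolment 140 at 10% attrition -> 126 evaluable -> same as n=63/arm
        d = _design(n_target_total=140, attrition_rate=0.1)
        es = backcalculate_target_es(d)
        assert es.value == pytest.approx(0.4992, abs=5e-4)
        assert "attrition_deflated_enrolment_total" in es.assumptions_applied

    def test_missing_n_is_insufficient_information(self):
        with pytest.raises(InsufficientInformationError):
            backcalculate_target_es(_design())

    def test_tiny_arms_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            backcalculate_target_es(_design(n_target_evaluable=3))


class TestForwardSampleSize:
    def test_classic_half_sd_design(self):
        assert forward_sample_size(0.5, _design()) == (63, 63)

    def test_attrition_inflation_divides_by_retention(self):
        d = _design(attrition_rate=0.1)
        assert forward_sample_size(0.5, d, inflate_attrition=True) == (70, 70)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            forward_sample_size(0.0, _design())

    def test_inversion_recovers_delta_within_ceiling_slack(self):
        # back-calculation composed with the forward formula: delta' <= delta,
        # with the gap bounded by the ceiling-induced slack, and exact when the
        # pre-ceiling sizes are integral
        rng = np.random.default_rng(20240817)
        checked = 0
        while checked < 1000:
            alpha = rng.uniform(0.01, 0.2)
            power = rng.uniform(0.55, 0.95)
            r = float(np.exp(rng.uniform(np.log(0.25), np.log(4.0))))
            delta = rng.uniform(0.1, 1.2)
            sided = "two" if rng.random() < 0.5 else "one"
            d = DesignParameters(
                alpha=alpha,
                sided=sided,
                power=power,
                allocation_ratio=r,
                outcome_type="continuous",
            )
            n1, n2 = forward_sample_size(delta, d)
            if n1 < 2 or n2 < 2:
                continue
            back = backcalculate_target_es(
                d.model_copy(update={"n_target_evaluable": n1 + n2})
            ).value
            assert back <= delta + 1e-12
            cv = critical_values(alpha, sided, power)
            x = cv.total**2 * (1 + 1 / r) / delta**2  # pre-ceiling n1
            lower = delta * math.sqrt(
                x * (1 / (x + 1) + 1 / (r * (x + 1) + 1)) / (1 + 1 / r)
            )
            assert back >= lower - 1e-12
            checked += 1

    def test_inversion_exact_for_integral_designs(self):
        d = _design()
        cv = critical_values(0.05, "two", 0.8)
        delta = cv.total * math.sqrt(2 / 50)  # pre-ceiling n1 = exactly 50
        n1, n2 = forward_sample_size(delta, d)
        assert (n1, n2) == (50, 50)
        back = backcalculate_target_es(d.model_copy(update={"n_target_evaluable": 100}))
        assert back.value == pytest.approx(delta, abs=1e-12)


class TestRatioConversions:
    def test_unit_odds_ratio_maps_to_zero(self):
        assert target_es_from_binary(0.3, 0.3).value == 0.0

    def test_log_odds_scale_factor(self):
        # OR = e: p_c = 0.5 -> odds e -> p_t = e/(1+e)
        p_t = math.e / (1 + math.e)
        es = target_es_from_binary(0.5, p_t)
        assert es.value == pytest.approx(SQRT3_OVER_PI, abs=1e-10)
        assert es.provenance == "converted_log_odds"

    def test_boundary_rates_rejected_with_guidance(self):
        with pytest.raises(ValueError, match="continuity"):
            target_es_from_binary(0.0, 0.5)

    @given(
        p_c=st.floats(0.01, 0.99),
        p_t=st.floats(0.01, 0.99),
    )
    @settings(max_examples=200, deadline=None)
    def test_odds_conversion_symmetric_under_arm_swap(self, p_c, p_t):
        assert target_es_from_binary(p_c, p_t).value == pytest.approx(
            target_es_from_binary(p_t, p_c).value, abs=1e-12
        )

    def test_unit_hazard_ratio_maps_to_zero(self):
        assert target_es_from_hazard(1.0).value == 0.0

    def test_log_hazard_scale_factor(self):
        assert target_es_from_hazard(math.exp(-1)).value == pytest.approx(
            SQRT3_OVER_PI, abs=1e-10
        )

    @given(hr=st.floats(0.05, 20.0))
    @settings(max_examples=200, deadline=None)
    def test_hazard_conversion_symmetric_under_ratio_inversion(self, hr):
        assert target_es_from_hazard(hr).value == pytest.approx(
            target_es_from_hazard(1 / hr).value, abs=1e-10
        )

    def test_nonpositive_hazard_ratio_rejected(self):
        with pytest.raises(ValueError):
            target_es_from_hazard(0.0)


class TestStandardiseObserved:
    def test_z_statistic_route(self):
        r = OutcomeResult(test_statistic=1.96, n_achieved_per_arm=(50, 50))
        es = standardise_observed(r, _design())
        assert es.value == pytest.approx(1.96 * math.sqrt(0.04), abs=1e-10)
        assert es.provenance == "from_test_statistic"

    def test_two_sided_p_of_one_maps_to_zero(self):
        r = OutcomeResult(p_value=1.0, n_achieved_per_arm=(50, 50))
        es = standardise_observed(r, _design())
        assert es.value == 0.0
        assert es.provenance == "from_p_value"

    def test_means_and_pooled_sd_route(self):
        r = OutcomeResult(effect_estimate=2.0, sd_pooled=4.0, n_achieved_per_arm=(40, 40))
        d = _design(target_difference=5.0, variability_or_control_rate=10.0)
        es = standardise_observed(r, d)
        assert es.value == pytest.approx(0.5, abs=1e-12)
        assert es.provenance == "direct"

    def test_effect_reversal_carries_negative_sign(self):
        r = OutcomeResult(effect_estimate=-2.0, sd_pooled=4.0)
        d = _design(target_difference=5.0, variability_or_control_rate=10.0)
        assert standardise_observed(r, d).value == pytest.approx(-0.5)

    def test_hazard_ratio_reversal_is_negative(self):
        d = _design(outcome_type="time_to_event", target_difference=0.7)
        better = OutcomeResult(effect_estimate=0.8, se=0.1)
        worse = OutcomeResult(effect_estimate=1.25, se=0.1)
        assert standardise_observed(better, d).value > 0
        assert standardise_observed(worse, d).value < 0

    @given(
        z=st.floats(0.01, 4.0),
        n1=st.integers(5, 500),
        n2=st.integers(5, 500),
        two_sided=st.booleans(),
    )
    @settings(max_examples=200, deadline=None)
    def test_p_route_agrees_with_z_route_when_consistent(self, z, n1, n2, two_sided):
        s = 2.0 if two_sided else 1.0
        d = _design(sided="two" if two_sided else "one")
        p = float(s * (1 - norm.cdf(z)))
        if not 0.0 < p <= 1.0:
            return
        via_z = standardise_observed(
            OutcomeResult(test_statistic=z, n_achieved_per_arm=(n1, n2)), d
        )
        via_p = standardise_observed(
            OutcomeResult(
                p_value=p,
                n_achieved_per_arm=(n1, n2),
                direction_matches_hypothesis=True,
            ),
            d,
        )
        assert via_p.value == pytest.approx(via_z.value, abs=1e-10)

    def test_small_sample_t_statistic_routes_through_t_cdf(self):
        d = _design()
        t_small = OutcomeResult(
            test_statistic=2.1, test_statistic_df=10, n_achieved_per_arm=(6, 6)
        )
        z_like = OutcomeResult(test_statistic=2.1, n_achieved_per_arm=(6, 6))
        es_t = standardise_observed(t_small, d)
        es_z = standardise_observed(z_like, d)
        assert es_t.provenance == "from_p_value"
        assert 0 < es_t.value < es_z.value  # t tails are heavier than normal

    def test_no_route_is_insufficient_information(self):
        r = OutcomeResult(p_value=0.04, n_achieved_per_arm=(30, 30))
        r = r.model_copy(update={"n_achieved_per_arm": None, "test_statistic": 1.0})
        with pytest.raises(InsufficientInformationError):
            standardise_observed(r, _design())


class TestStandardiseTarget:
    def test_direct_continuous_ratio(self):
        d = _design(target_difference=5.0, variability_or_control_rate=10.0)
        es = standardise_target(d)
        assert es.value == pytest.approx(0.5, abs=1e-12)
        assert es.provenance == "direct"

    def test_back_calculated_when_only_design_parameters_given(self):
        es = standardise_target(_design(n_target_evaluable=126))
        assert es.provenance == "back_calculated"

    def test_zero_superiority_target_rejected(self):
        d = _design(target_difference=0.0, variability_or_control_rate=10.0)
        with pytest.raises(ValueError, match="strictly positive"):
            standardise_target(d)

    def test_consistency_diagnostic_flags_gross_mismatch(self):
        # direct target 0.50 but a sample size implying ~0.80
        d = _design(target_difference=5.0, variability_or_control_rate=10.0)
        n1, n2 = forward_sample_size(0.8, d)
        es = standardise_target(d.model_copy(update={"n_target_evaluable": n1 + n2}))
        assert es.diagnostic_backcalculated == pytest.approx(0.8, abs=0.01)
        assert consistency_mismatch(es, tolerance=0.2)
        consistent = standardise_target(
            d.model_copy(
                update={"n_target_evaluable": sum(forward_sample_size(0.5, d))}
            )
        )
        assert not consistency_mismatch(consistent, tolerance=0.2)

    @given(k=st.floats(0.1, 50.0))
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance_of_continuous_target(self, k):
        base = standardise_target(
            _design(target_difference=5.0, variability_or_control_rate=10.0)
        ).value
        scaled = standardise_target(
            _design(target_difference=5.0 * k, variability_or_control_rate=10.0 * k)
        ).value
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_defaults_propagate_to_assumptions(self):
        es = standardise_target(
            _design(alpha=None, sided=None, n_target_evaluable=126)
        )
        assert "alpha_defaulted" in es.assumptions_applied
        assert "sided_defaulted" in es.assumptions_applied
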