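"""Validation, imputation, heart-age inversion and reporting tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heartage.engine import (
    ELIGIBILITY_WARNING,
    HIGH_RISK_ADVISORY,
    RANGE_ERROR,
    HeartAgeBounds,
    IdealProfile,
    assess,
    categorize,
    heart_age,
    ideal_risk_at_age,
    impute_unknowns,
    render_report,
    round_half_away,
    validate_inputs,
)
from heartage.errors import ConfigurationError
from heartage.risk import RiskProfile, linear_predictor


def _profile(**kw):
    base = dict(age=50, sex="female", sbp=125.0, total_cholesterol=5.0)
    base.update(kw)
    return RiskProfile(**base)


class TestValidation:
    def test_implausible_cholesterol_gives_exact_range_message(self):
        msgs = validate_inputs(_profile(total_cholesterol=1.5))
        assert len(msgs) == 1
        assert msgs[0].severity == RANGE_ERROR
        assert msgs[0].message == "Please enter a number between 2 and 10.5"
        assert msgs[0].blocks_calculation

    def test_high_cholesterol_advisory_wording(self):
        msgs = validate_inputs(_profile(total_cholesterol=8.0))
        assert len(msgs) == 1
        assert msgs[0].severity == HIGH_RISK_ADVISORY
        assert "above 7.5 mmol/L" in msgs[0].message
        assert msgs[0].message == (
            "Total cholesterol above 7.5 mmol/L puts you at high risk of "
            "having a heart attack or stroke. Please see your doctor as soon "
            "as possible about your cholesterol."
        )
        assert not msgs[0].blocks_calculation

    def test_all_plausible_values_give_no_messages(self):
        assert validate_inputs(_profile()) == []

    @pytest.mark.parametrize("value,severity", [
        (300.0, RANGE_ERROR), (60.0, RANGE_ERROR), (190.0, HIGH_RISK_ADVISORY),
    ])
    def test_sbp_rules_from_config_defaults(self, value, severity):
        msgs = validate_inputs(_profile(sbp=value))
        assert [m.severity for m in msgs] == [severity]

    @pytest.mark.parametrize("age", [30, 80])
    def test_age_outside_target_range_warns_without_blocking(self, age):
        msgs = validate_inputs(_profile(age=age))
        assert [m.severity for m in msgs] == [ELIGIBILITY_WARNING]
        assert not msgs[0].blocks_calculation

    def test_unknown_values_are_not_validated(self):
        msgs = validate_inputs(_profile(sbp=None, total_cholesterol=None))
        assert msgs == []


class TestImputation:
    def test_known_values_pass_through_hdl_always_filled(self, model):
        profile = _profile()
        out = impute_unknowns(profile, model.imputation)
        assert out.sbp == profile.sbp
        assert out.total_cholesterol == profile.total_cholesterol
        assert out.hdl_cholesterol is not None
        assert out.sbp_known and out.cholesterol_known

    def test_unknown_cholesterol_takes_band_mean(self, model):
        out = impute_unknowns(
            _profile(age=52, total_cholesterol=None), model.imputation
        )
        expected = model.imputation.bands[("female", 50)]["total_cholesterol"]
        assert out.total_cholesterol == expected
        assert not out.cholesterol_known  # flag preserved for reporting

    def test_both_unknown_equal_direct_table_read(self, model):
        for age in (35, 41, 58, 75):
            out = impute_unknowns(
                _profile(age=age, sex="male", sbp=None, total_cholesterol=None),
                model.imputation,
            )
            band = model.imputation.lookup("male", age)
            assert out.sbp == band["sbp"]
            assert out.total_cholesterol == band["total_cholesterol"]
            assert out.hdl_cholesterol == band["hdl_cholesterol"]

    def test_missing_band_is_configuration_error(self, model):
        from heartage.engine import ImputationTable

        bands = dict(model.imputation.bands)
        del bands[("female", 50)]
        with pytest.raises(ConfigurationError):
            ImputationTable(bands=bands)


class TestIdealRisk:
    def test_zero_beta_config_constant_in_age(self, zero_beta_coeffs):
        risks = {
            age: ideal_risk_at_age(age, "female", zero_beta_coeffs).risk
            for age in (35, 55, 75)
        }
        assert all(r == pytest.approx(0.1, abs=1e-12) for r in risks.values())

    def test_strictly_increasing_in_age(self, coeffs):
        for sex in ("female", "male"):
            r40 = ideal_risk_at_age(40, sex, coeffs).risk
            r60 = ideal_risk_at_age(60, sex, coeffs).risk
            assert r60 > r40

    def test_curve_matches_direct_equation_evaluation(self, coeffs):
        """Ideal-risk curve vs. an independent closed-form computation."""
        ideal = IdealProfile()
        for sex in ("female", "male"):
            eq = coeffs.equation_for(sex)
            betas = {t.name: t.beta for t in eq.terms}
            for age in (35, 45, 55, 65, 75):
                lp = (
                    betas["age"] * math.log(age)
                    + betas["total_cholesterol"] * math.log(4.0 * 38.67)
                    + betas["hdl_cholesterol"] * math.log(1.3 * 38.67)
                    + betas["sbp"] * math.log(120.0)
                )
                expected = 1 - eq.baseline_survival ** math.exp(lp - eq.lp_mean)
                assert ideal_risk_at_age(age, sex, coeffs, ideal).risk == (
                    pytest.approx(expected, abs=1e-12)
                )


class TestRounding:
    @pytest.mark.parametrize("value,expected", [
        (54.4, 54), (54.5, 55), (54.6, 55), (0.5, 1), (-0.5, -1), (35.0, 35),
    ])
    def test_round_half_away(self, value, expected):
        assert round_half_away(value) == expected

    @pytest.mark.parametrize("raw,age,expected", [
        (54.4, 54, "equal"), (59.6, 54, "older"), (50.2, 54, "younger"),
        (54.5, 54, "older"), (53.5, 54, "equal"),
    ])
    def test_categorize(self, raw, age, expected):
        assert categorize(raw, age) == expected


class TestHeartAge:
    def test_inversion_identity_across_ages_and_sexes(self, model):
        for sex in ("female", "male"):
            for age in range(35, 76):
                profile = model.ideal.at_age(age, sex)
                result = heart_age(
                    profile, model.coefficients, model.ideal, model.bounds
                )
                assert result.heart_age_raw == pytest.approx(age, abs=0.01)
                assert result.category == "equal"

    def test_risk_matching_when_uncensored(self, model):
        profile = _profile(age=55, sbp=135.0, total_cholesterol=5.5,
                           hdl_cholesterol=1.3)
        result = heart_age(profile, model.coefficients, model.ideal, model.bounds)
        assert result.bracket_censored is None
        back = ideal_risk_at_age(
            result.heart_age_raw, "female", model.coefficients, model.ideal
        )
        assert back.risk == pytest.approx(result.risk.risk, abs=1e-9)

    def test_smoking_raises_heart_age_above_chronological(self, model):
        profile = model.ideal.at_age(50, "male").replace(smoker=True)
        result = heart_age(profile, model.coefficients, model.ideal, model.bounds)
        assert result.heart_age_raw > 50
        assert result.category == "older"

    @given(
        age=st.floats(35, 75),
        sbp=st.floats(90, 200),
        tc=st.floats(2.5, 10),
        hdl=st.floats(0.6, 2.5),
        smoker=st.booleans(),
        diabetes=st.booleans(),
        sex=st.sampled_from(["female", "male"]),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_bisection_matches_closed_form_log_age_inversion(
        self, log_age_coeffs, age, sbp, tc, hdl, smoker, diabetes, sex
    ):
        """With the only age term beta*ln(age), the inversion has the
        analytic solution ln(a*) = (LP_profile - LP_ideal_nonage) / beta."""
        ideal = IdealProfile()
        bounds = HeartAgeBounds(solver_min=5.0, solver_max=200.0)
        profile = RiskProfile(
            age=age, sex=sex, sbp=sbp, total_cholesterol=tc,
            hdl_cholesterol=hdl, smoker=smoker, diabetes=diabetes,
        )
        beta_age = 2.5
        lp_profile = linear_predictor(profile, log_age_coeffs)
        # ideal profile at age 1: ln(1) = 0 isolates the non-age terms
        lp_ideal_base = linear_predictor(ideal.at_age(1.0, sex), log_age_coeffs)
        closed_form = math.exp((lp_profile - lp_ideal_base) / beta_age)
        if not bounds.solver_min < closed_form < bounds.solver_max:
            return
        result = heart_age(profile, log_age_coeffs, ideal, bounds)
        assert result.heart_age_raw == pytest.approx(closed_form, abs=1e-6)

    def test_monotone_in_each_positive_beta_factor(self, model):
        base = _profile(age=55, sbp=130.0, total_cholesterol=5.5,
                        hdl_cholesterol=1.3)
        base_result = heart_age(base, model.coefficients, model.ideal, model.bounds)
        for change in (
            {"sbp": 145.0}, {"total_cholesterol": 6.5},
            {"smoker": True}, {"diabetes": True},
        ):
            worse = heart_age(
                base.replace(**change), model.coefficients, model.ideal,
                model.bounds,
            )
            assert worse.heart_age_raw >= base_result.heart_age_raw

    def test_censoring_display_and_raw_retained(self, model):
        extreme = _profile(
            age=75, sex="male", smoker=True, diabetes=True, sbp=200.0,
            total_cholesterol=10.0, hdl_cholesterol=0.7, on_bp_medication=True,
        )
        high = heart_age(extreme, model.coefficients, model.ideal, model.bounds)
        assert high.heart_age_display == "≥85"
        assert high.heart_age_raw >= 85 or high.bracket_censored == "high"
        # sub-ideal young profile: better-than-ideal values push below 35
        young = _profile(
            age=35, sbp=95.0, total_cholesterol=2.8, hdl_cholesterol=2.5,
        )
        low = heart_age(young, model.coefficients, model.ideal, model.bounds)
        assert low.heart_age_display == "<35"
        assert math.isfinite(low.heart_age_raw)
        assert low.category == "younger"

    def test_out_of_bracket_risk_clamps_without_exception(self, model):
        bounds = HeartAgeBounds(solver_min=40.0, solver_max=60.0)
        young = _profile(age=35, sbp=95.0, total_cholesterol=2.8,
                         hdl_cholesterol=2.5)
        result = heart_age(young, model.coefficients, model.ideal, bounds)
        assert result.bracket_censored == "low"
        assert result.heart_age_raw == 40.0

    def test_flat_ideal_risk_is_configuration_error(self, model, zero_beta_coeffs):
        with pytest.raises(ConfigurationError):
            heart_age(_profile(hdl_cholesterol=1.3), zero_beta_coeffs)


class TestAssessAndReport:
    def test_blocked_on_range_error(self, model):
        result = assess(_profile(total_cholesterol=1.5), model)
        assert result.blocked
        assert result.heart_age_display == ""
        assert result.advisories[0].severity == RANGE_ERROR

    def test_advisory_does_not_block(self, model):
        result = assess(_profile(total_cholesterol=8.0), model)
        assert not result.blocked
        assert any(m.severity == HIGH_RISK_ADVISORY for m in result.advisories)

    def test_report_older_result_recommends_doctor(self, model):
        profile = _profile(age=50, smoker=True, sbp=160.0, total_cholesterol=7.0)
        result = assess(profile, model)
        assert result.category == "older"
        report = render_report(result, impute_unknowns(profile, model.imputation))
        assert "heart health check" in report
        assert "see your doctor" in report

    def test_report_flags_population_average(self, model):
        profile = _profile(sbp=None, total_cholesterol=None)
        result = assess(profile, model)
        report = render_report(result, impute_unknowns(profile, model.imputation))
        assert "population average" in report

    def test_report_equal_category_sentence(self, model):
        profile = model.ideal.at_age(50, "female")
        result = heart_age(profile, model.coefficients, model.ideal, model.bounds)
        assert result.category == "equal"
        report = render_report(result, profile)
        assert "SAME as your current age" in report
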