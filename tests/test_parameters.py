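"""Unit tests for parameter types, conversions, and (de)serialization."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from cardiovert.params import (
    DemographicsBand, EventRates, EventInput, ParameterSet, UncertainParameter,
    ValidationError, annual_prob_to_cycle_prob, annual_rate_to_cycle_prob,
    annual_to_cycle, beta_from_mean_se, continuation_fraction, default_se,
    gamma_from_mean_se, load_parameter_set, parameter_set_from_dict,
    parameter_set_to_dict, pval, save_parameter_set, validation_report,
)


# --------------------------------------------------------------------------
# conversions
# --------------------------------------------------------------------------

class TestConversions:
    def test_rate_to_daily_prob_frozen(self):
        # 1 - exp(-0.0365/365) = 1 - exp(-1e-4)
        assert annual_rate_to_cycle_prob(0.0365, 1) == pytest.approx(
            9.9995000333e-05, rel=1e-9)

    def test_rate_to_annual_prob_frozen(self):
        assert annual_rate_to_cycle_prob(0.05, 365) == pytest.approx(
            1.0 - math.exp(-0.05), rel=1e-12)

    def test_prob_to_weekly_prob_frozen(self):
        # independent closed form: 1 - (1-p)^(7/365)
        assert annual_prob_to_cycle_prob(0.05, 7) == pytest.approx(
            1.0 - 0.95 ** (7.0 / 365.0), rel=1e-12)

    def test_prob_edge_cases(self):
        assert annual_prob_to_cycle_prob(0.0, 7) == 0.0
        assert annual_prob_to_cycle_prob(1.0, 7) == 1.0
        assert annual_rate_to_cycle_prob(0.0, 1) == 0.0

    def test_weekly_equals_compounded_daily(self):
        for p in (0.01, 0.2, 0.8):
            p1 = annual_prob_to_cycle_prob(p, 1)
            p7 = annual_prob_to_cycle_prob(p, 7)
            assert 1.0 - (1.0 - p1) ** 7 == pytest.approx(p7, rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            annual_rate_to_cycle_prob(-0.1, 1)
        with pytest.raises(ValueError):
            annual_rate_to_cycle_prob(0.1, 0.5)
        with pytest.raises(ValueError):
            annual_prob_to_cycle_prob(1.2, 7)
        with pytest.raises(ValueError):
            annual_to_cycle(0.1, "hazard", 1)

    @settings(deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0), d=st.floats(1.0, 365.0))
    def test_prob_conversion_stays_in_unit_interval(self, p, d):
        q = annual_prob_to_cycle_prob(p, d)
        assert 0.0 <= q <= 1.0
        assert q <= p + 1e-12  # shorter cycles never exceed the annual prob

    @settings(deadline=None, derandomize=True)
    @given(r=st.floats(0.0, 10.0))
    def test_rate_conversion_monotone(self, r):
        assert annual_rate_to_cycle_prob(r, 7) <= annual_rate_to_cycle_prob(
            r + 0.1, 7)


class TestMomentMatching:
    def test_beta_uniform_frozen(self):
        # mean 1/2, variance 1/12 -> Beta(1, 1)
        a, b = beta_from_mean_se(0.5, math.sqrt(1.0 / 12.0))
        assert a == pytest.approx(1.0, rel=1e-12)
        assert b == pytest.approx(1.0, rel=1e-12)

    def test_beta_frozen(self):
        # nu = 0.8*0.2/0.01 - 1 = 15 -> (12, 3)
        a, b = beta_from_mean_se(0.8, 0.1)
        assert a == pytest.approx(12.0, rel=1e-12)
        assert b == pytest.approx(3.0, rel=1e-12)

    def test_beta_infeasible(self):
        with pytest.raises(ValueError):
            beta_from_mean_se(0.5, 0.5)
        with pytest.raises(ValueError):
            beta_from_mean_se(0.0, 0.1)
        with pytest.raises(ValueError):
            beta_from_mean_se(0.5, 0.0)

    def test_gamma_frozen(self):
        # shape (100/10)^2 = 100, scale 100/100 = 1
        shape, scale = gamma_from_mean_se(100.0, 10.0)
        assert shape == pytest.approx(100.0, rel=1e-12)
        assert scale == pytest.approx(1.0, rel=1e-12)

    def test_gamma_invalid(self):
        with pytest.raises(ValueError):
            gamma_from_mean_se(0.0, 1.0)
        with pytest.raises(ValueError):
            gamma_from_mean_se(10.0, 0.0)

    @settings(deadline=None, derandomize=True)
    @given(mean=st.floats(0.01, 0.99), frac=st.floats(0.01, 0.5))
    def test_beta_moments_round_trip(self, mean, frac):
        se = frac * math.sqrt(mean * (1 - mean))
        a, b = beta_from_mean_se(mean, se)
        assert a / (a + b) == pytest.approx(mean, rel=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert var == pytest.approx(se * se, rel=1e-9)


class TestDefaultSE:
    def test_fills_fraction_of_mean(self):
        u = default_se(UncertainParameter(mean=0.4, family="beta"), 0.15)
        assert u.se == pytest.approx(0.06)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            default_se(UncertainParameter(mean=0.4), 0.25)

    def test_refuses_overwrite(self):
        with pytest.raises(ValueError):
            default_se(UncertainParameter(mean=0.4, se=0.02, family="beta"))


class TestContinuationFraction:
    def test_frozen_base_case(self):
        # 1 - (0.74*0.026 + 0.26*0.127) = 0.94774
        assert continuation_fraction(0.74, 0.026, 0.127) == pytest.approx(
            0.94774, abs=1e-12)

    def test_all_continue_when_everyone_scores(self):
        assert continuation_fraction(0.5, 0.0, 0.0) == 1.0

    def test_invalid(self):
        with pytest.raises(ValueError):
            continuation_fraction(1.5, 0.0, 0.0)
        with pytest.raises(ValueError):
            continuation_fraction(0.5, 0.3, 0.1)


class TestUncertainParameter:
    def test_pval(self):
        assert pval(UncertainParameter(mean=0.3)) == 0.3
        assert pval(0.7) == 0.7

    def test_validation(self):
        with pytest.raises(ValidationError):
            UncertainParameter(mean=0.5, family="lognormal")
        with pytest.raises(ValidationError):
            UncertainParameter(mean=0.5, se=-0.1)
        with pytest.raises(ValidationError):
            UncertainParameter(mean=1.5, family="beta")
        with pytest.raises(ValidationError):
            UncertainParameter(mean=0.5, se=0.6, family="beta")
        with pytest.raises(ValidationError):
            UncertainParameter(mean=-1.0, family="gamma")


class TestMortalityLookup:
    def test_step_function(self):
        ev = EventRates(is_=EventInput(0.0), mi=EventInput(0.0),
                        ich=EventInput(0.0), mah=EventInput(0.0),
                        gih=EventInput(0.0), mih=EventInput(0.0),
                        mortality=[(60.0, 0.01), (65.0, 0.02)])
        assert ev.mortality_annual_prob(59.0) == 0.01   # first band extends down
        assert ev.mortality_annual_prob(64.9) == 0.01
        assert ev.mortality_annual_prob(65.0) == 0.02
        assert ev.mortality_annual_prob(90.0) == 0.02   # last band extends up

    def test_empty_table_raises(self):
        ev = EventRates(is_=EventInput(0.0), mi=EventInput(0.0),
                        ich=EventInput(0.0), mah=EventInput(0.0),
                        gih=EventInput(0.0), mih=EventInput(0.0), mortality=[])
        with pytest.raises(ValidationError):
            ev.mortality_annual_prob(60.0)


# --------------------------------------------------------------------------
# validation and (de)serialization
# --------------------------------------------------------------------------

class TestValidation:
    def test_generated_sets_pass(self, base_ps, bundled_ps):
        base_ps.validate()
        bundled_ps.validate()
        assert "FAIL" not in validation_report(base_ps)

    def test_broken_set_fails(self, base_ps):
        import copy
        bad = copy.deepcopy(base_ps)
        bad.cohort.male_share = 1.5
        with pytest.raises(ValidationError):
            bad.validate()
        assert "FAIL" in validation_report(bad)

    def test_bundled_base_case_pins(self, bundled_ps):
        assert bundled_ps.arms["riva"].pre_ecv_days == 22
        assert bundled_ps.arms["vka"].pre_ecv_days == 30
        assert not bundled_ps.arms["riva"].inr_monitored
        assert bundled_ps.arms["vka"].inr_monitored
        assert bundled_ps.wtp == 20_000.0


class TestSerialization:
    def test_yaml_round_trip(self, base_ps, tmp_path):
        path = tmp_path / "config.yaml"
        save_parameter_set(base_ps, path)
        loaded = load_parameter_set(path)
        assert parameter_set_to_dict(loaded) == parameter_set_to_dict(base_ps)

    def test_unknown_key_rejected(self, base_ps):
        doc = parameter_set_to_dict(base_ps)
        doc["typo_section"] = 1
        with pytest.raises(ValidationError, match="unknown keys"):
            parameter_set_from_dict(doc)

    def test_unknown_nested_key_rejected(self, base_ps):
        doc = parameter_set_to_dict(base_ps)
        doc["cohort"]["mean_age"] = 64.0
        with pytest.raises(ValidationError, match="unknown keys"):
            parameter_set_from_dict(doc)

    def test_missing_required_rejected(self, base_ps):
        doc = parameter_set_to_dict(base_ps)
        del doc["events"]
        with pytest.raises(ValidationError, match="missing required"):
            parameter_set_from_dict(doc)

    def test_missing_wtp_defaults_with_notice(self, base_ps):
        doc = parameter_set_to_dict(base_ps)
        del doc["wtp"]
        ps = parameter_set_from_dict(doc)
        assert ps.wtp == 20_000.0
        assert any("wtp" in n for n in ps.metadata.get("notices", []))

    def test_unknown_arm_rejected(self, base_ps):
        doc = parameter_set_to_dict(base_ps)
        doc["arms"]["apixaban"] = doc["arms"]["riva"]
        with pytest.raises(ValidationError, match="unknown arm"):
            parameter_set_from_dict(doc)


class TestDemographicsBand:
    def test_fields(self):
        b = DemographicsBand(60, 65, 0.52, 31, 3600)
        assert b.age_hi == 65
        assert b.participation == 0.52
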