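"""Tests for the synthetic parameter generator and derived-input arithmetic."""

import pytest

from cardiovert.params import parameter_set_to_dict, pval
from cardiovert.synth import (
    generate_parameter_set, informal_care_cost, inr_monitoring_cost,
    productivity_loss_unit_cost, provenance, weighted_state_utility,
)
from cardiovert.params import DemographicsBand


class TestWeightedStateUtility:
    def test_frozen_value(self):
        # 0.7*0.5 + 0.6*0.3 + 0.5*0.2 = 0.63
        assert weighted_state_utility([0.7, 0.6, 0.5], [0.5, 0.3, 0.2]) \
            == pytest.approx(0.63, abs=1e-12)

    def test_weight_rescaling_invariance(self):
        u = [0.9, 0.7, 0.4]
        a = weighted_state_utility(u, [0.2, 0.5, 0.3])
        b = weighted_state_utility(u, [2.0, 5.0, 3.0])
        assert a == pytest.approx(b, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            weighted_state_utility([0.5], [0.5, 0.5])
        with pytest.raises(ValueError):
            weighted_state_utility([0.5, 0.5], [-0.1, 1.1])
        with pytest.raises(ValueError):
            weighted_state_utility([0.5, 0.5], [0.0, 0.0])


class TestInrMonitoringCost:
    def test_per_year_frozen(self):
        # 0.569*21.1*10 + 0.431*23.5*10 = 221.344
        assert inr_monitoring_cost(unit_cost_service=10.0, unit_cost_home=10.0,
                                   period="per_year") \
            == pytest.approx(221.344, abs=1e-9)

    def test_pre_ecv_frozen(self):
        # 5.5 measurements at a blended 12 euro each
        assert inr_monitoring_cost(unit_cost_service=12.0, unit_cost_home=12.0,
                                   period="pre_ecv") == pytest.approx(66.0)

    def test_cycle_proration(self):
        full = inr_monitoring_cost(unit_cost_service=10.0, unit_cost_home=12.0,
                                   period="per_year")
        week = inr_monitoring_cost(unit_cost_service=10.0, unit_cost_home=12.0,
                                   period="per_year", cycle_days=7)
        assert week == pytest.approx(full * 7.0 / 365.0, rel=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            inr_monitoring_cost(unit_cost_service=-1.0, unit_cost_home=1.0)
        with pytest.raises(ValueError):
            inr_monitoring_cost(unit_cost_service=1.0, unit_cost_home=1.0,
                                mix_service=0.6, mix_home=0.6)
        with pytest.raises(ValueError):
            inr_monitoring_cost(unit_cost_service=1.0, unit_cost_home=1.0,
                                period="per_month")


class TestProductivityUnitCost:
    def test_single_band_frozen(self):
        # hours cancel: 0.5 participation * 4000 euro/month * 12/52
        band = [DemographicsBand(15, 67, 0.5, 40, 4000)]
        assert productivity_loss_unit_cost(band) \
            == pytest.approx(0.5 * 4000 * 12 / 52, rel=1e-12)

    def test_hours_do_not_matter(self):
        a = productivity_loss_unit_cost([DemographicsBand(15, 67, 0.5, 20, 4000)])
        b = productivity_loss_unit_cost([DemographicsBand(15, 67, 0.5, 40, 4000)])
        assert a == pytest.approx(b)

    def test_age_weighting_prefers_nearby_bands(self):
        bands = [DemographicsBand(15, 40, 1.0, 38, 1000),
                 DemographicsBand(40, 67, 1.0, 38, 5000)]
        young = productivity_loss_unit_cost(bands, mean_age=30, sd_age=5)
        old = productivity_loss_unit_cost(bands, mean_age=60, sd_age=5)
        assert young < old

    def test_errors(self):
        with pytest.raises(ValueError):
            productivity_loss_unit_cost([])
        with pytest.raises(ValueError):
            productivity_loss_unit_cost([DemographicsBand(70, 80, 0.1, 10, 1000)])


class TestInformalCareCost:
    def test_frozen_values(self):
        assert informal_care_cost("intensive", 15.0, 10.0) == pytest.approx(3900.0)
        assert informal_care_cost("nonintensive", 15.0, 1.0) == pytest.approx(120.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            informal_care_cost("heavy", 15.0, 1.0)
        with pytest.raises(ValueError):
            informal_care_cost("intensive", 15.0, -1.0)


class TestGenerator:
    def test_deterministic_given_seed(self):
        a = generate_parameter_set(123)
        b = generate_parameter_set(123)
        assert parameter_set_to_dict(a) == parameter_set_to_dict(b)

    def test_seeds_differ(self):
        a = generate_parameter_set(1)
        b = generate_parameter_set(2)
        assert parameter_set_to_dict(a) != parameter_set_to_dict(b)

    @pytest.mark.parametrize("seed", [0, 7, 99])
    def test_headline_quantities_pinned(self, seed):
        ps = generate_parameter_set(seed)
        assert ps.cohort.start_age == 64.4
        assert pval(ps.cohort.male_share) == 0.74
        assert ps.arms["riva"].pre_ecv_days == 22
        assert ps.arms["vka"].pre_ecv_days == 30
        assert pval(ps.arms["vka"].p_inadequate_first) == 0.4419
        assert pval(ps.arms["vka"].p_inadequate_second) == 0.20
        assert pval(ps.arms["riva"].p_inadequate_first) == 0.0024
        assert pval(ps.ecv.p_success) == 0.864
        assert ps.wtp == 20_000.0
        assert ps.continuation_fraction() == pytest.approx(0.94774)

    def test_stress_preset_pins_events_high(self):
        from cardiovert.synth import _RANGES
        ps = generate_parameter_set(5, "stress")
        for ev, (_, hi) in _RANGES["events"].items():
            assert pval(getattr(ps.events, ev).value) == hi

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            generate_parameter_set(1, "worst_case")

    def test_fuzz_many_seeds_valid(self):
        for seed in range(300):
            ps = generate_parameter_set(seed)
            ps.validate()  # raises on any violation
            # structural sanity beyond validate()
            u = ps.utilities
            assert pval(u.symptomatic_af) <= pval(u.asymptomatic_af)
            assert pval(u.symptomatic_af) <= pval(u.permanent_af) \
                <= pval(u.asymptomatic_af)
            cu = u.mehra.utilities
            order = [cu[c] for c in ("1", "2a", "2b", "3", "4")]
            assert order == sorted(order, reverse=True)
            assert sum(u.mehra.weights.values()) == pytest.approx(1.0)

    def test_provenance_labels(self):
        ps = generate_parameter_set(1)
        prov = provenance(ps)
        assert prov["ecv.p_success"] == "printed-value"
        assert prov["costs.ecv_tariff"] == "synthetic-plausible"
        assert set(prov.values()) == {"printed-value", "synthetic-plausible"}
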