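"""Cohort-engine tests: conservation, scheduling, single-cycle operations,
and the forced-path analytic check."""

import numpy as np
import pytest

from cardiovert import generate_parameter_set
from cardiovert.engine import (
    NS, S, build_model, ecv_attempt_split, post_ecv_weekly_step,
    pre_ecv_daily_step, run_cohort,
)
from cardiovert.sensitivity import apply_overrides

from conftest import equalized_arms


def _trace(ps, arm):
    return run_cohort(build_model(ps, arm))


# --------------------------------------------------------------------------
# invariants on full runs
# --------------------------------------------------------------------------

@pytest.mark.parametrize("seed", [1, 2])
@pytest.mark.parametrize("arm", ["riva", "vka"])
class TestConservation:
    def test_unit_mass_conserved_daily(self, seed, arm):
        ps = generate_parameter_set(seed)
        occ = _trace(ps, arm).daily_occupancy()
        total = occ.sum(axis=1)
        assert np.abs(total - 1.0).max() < 1e-10

    def test_no_resurrection(self, seed, arm):
        ps = generate_parameter_set(seed)
        occ = _trace(ps, arm).daily_occupancy()
        dead = occ[:, 1 + S.DEAD]
        assert (np.diff(dead) >= -1e-12).all()

    def test_ecv_attempts_bounded(self, seed, arm):
        ps = generate_parameter_set(seed)
        totals = _trace(ps, arm).ledger_totals()
        performed = totals.get("ecv_performed", 0.0)
        assert 0.0 < performed <= ps.schedule.max_attempts


class TestSymptomaticTimeMonotonicity:
    def test_more_vka_inadequacy_means_more_af_time(self, base_ps):
        prev = -np.inf
        for p in (0.1, 0.3, 0.5, 0.7):
            ps = apply_overrides(base_ps, {"arms.vka.p_inadequate_first": p})
            spd = _trace(ps, "vka").state_person_days()
            sym = (spd["waiting"] + spd["recur_on"] + spd["recur_off"]
                   + spd["perm_on"] + spd["perm_off"])
            assert sym > prev
            prev = sym


class TestArmSymmetry:
    def test_identical_arms_identical_traces(self, base_ps):
        ps = equalized_arms(base_ps)
        tr_r = _trace(ps, "riva")
        tr_v = _trace(ps, "vka")
        assert np.array_equal(tr_r.wait, tr_v.wait)
        assert np.array_equal(tr_r.post_occ, tr_v.post_occ)
        assert np.array_equal(tr_r.post_flows, tr_v.post_flows)
        assert tr_r.ledger_totals() == tr_v.ledger_totals()


# --------------------------------------------------------------------------
# single-cycle operations
# --------------------------------------------------------------------------

class TestEcvAttemptSplit:
    def test_frozen_split(self, base_ps):
        model = build_model(base_ps, "vka")
        # p_inadequate_first = 0.4419, p_success = 0.864
        split = ecv_attempt_split(1.0, 1, model)
        assert split["inadequate"] == pytest.approx(0.4419, abs=1e-12)
        assert split["performed"] == pytest.approx(0.5581, abs=1e-12)
        assert split["success"] == pytest.approx(0.5581 * 0.864, abs=1e-12)
        assert split["failed"] == pytest.approx(0.5581 * 0.136, abs=1e-12)

    def test_split_conserves_mass(self, base_ps):
        model = build_model(base_ps, "riva")
        split = ecv_attempt_split(0.7, 2, model)
        assert split["inadequate"] + split["success"] + split["failed"] \
            == pytest.approx(0.7, abs=1e-12)

    def test_attempt_out_of_range(self, base_ps):
        model = build_model(base_ps, "riva")
        with pytest.raises(ValueError):
            ecv_attempt_split(1.0, 3, model)
        with pytest.raises(ValueError):
            ecv_attempt_split(1.0, 0, model)


class TestPreEcvDailyStep:
    def test_conserves_mass(self, base_ps):
        model = build_model(base_ps, "vka")
        surv, exits = pre_ecv_daily_step(0.8, 5, model)
        leaving = sum(v for k, v in exits.items() if k != "mih")
        assert surv + leaving == pytest.approx(0.8, abs=1e-14)

    def test_proportional_allocation(self, forced_ps):
        import copy
        from cardiovert.params import EventInput
        ps = copy.deepcopy(forced_ps)
        ps.events.is_ = EventInput(value=0.10, kind="prob")
        ps.events.mah = EventInput(value=0.05, kind="prob")
        model = build_model(ps, "riva")
        _, exits = pre_ecv_daily_step(1.0, 0, model)
        # proportional-to-p allocation preserves the ratio of the daily probs
        assert exits["is_"] / exits["mah"] == pytest.approx(
            model.p_day["is_"] / model.p_day["mah"], rel=1e-12)

    def test_zero_probs_zero_exits(self, forced_ps):
        model = build_model(forced_ps, "riva")
        surv, exits = pre_ecv_daily_step(1.0, 0, model)
        assert surv == 1.0
        assert all(v == 0.0 for v in exits.values())


class TestPostEcvWeeklyStep:
    def test_conserves_mass_rowwise(self, base_ps):
        model = build_model(base_ps, "vka")
        rng = np.random.default_rng(0)
        occ = rng.dirichlet(np.ones(NS), size=4)
        qw = np.full(4, float(model.q_week[0]))
        new, flows = post_ecv_weekly_step(occ, qw, model)
        assert np.abs(new.sum(axis=1) - occ.sum(axis=1)).max() < 1e-12
        assert flows.shape == (4, 6)
        assert (flows >= 0).all()

    def test_ich_discontinues_anticoagulation(self, base_ps):
        model = build_model(base_ps, "vka")
        occ = np.zeros((1, NS))
        occ[0, S.SINUS_ON] = 1.0
        new, _ = post_ecv_weekly_step(occ, np.array([0.0]), model)
        # all incident ICH mass sits in the single (off-treatment) ICH state
        assert new[0, S.ICH] > 0


# --------------------------------------------------------------------------
# model construction and forced-path analytics
# --------------------------------------------------------------------------

class TestBuildModel:
    def test_unknown_arm(self, base_ps):
        with pytest.raises(ValueError):
            build_model(base_ps, "apixaban")

    def test_horizon_too_short(self, base_ps):
        import copy
        ps = copy.deepcopy(base_ps)
        ps.arms["riva"].pre_ecv_days = 200
        with pytest.raises(ValueError, match="horizon"):
            build_model(ps, "riva")

    def test_mortality_advances_with_age(self, base_ps):
        model = build_model(base_ps, "riva")
        assert model.q_day[-1] >= model.q_day[0]
        assert model.q_week[0] == pytest.approx(
            1.0 - (1.0 - model.q_day[0]) ** 7, rel=1e-12)


class TestForcedPathAnalytic:
    """With all event probabilities zero, every first ECV adequate and
    successful, and no recurrence, the whole cohort waits exactly D days and
    then sits in sinus rhythm; occupancy has a closed form."""

    @pytest.mark.parametrize("arm", ["riva", "vka"])
    def test_occupancy_matches_closed_form(self, forced_ps, arm):
        H = forced_ps.schedule.horizon_weeks * 7
        D = forced_ps.arms[arm].pre_ecv_days
        cf = forced_ps.continuation_fraction()
        spd = _trace(forced_ps, arm).state_person_days()
        assert spd["waiting"] == pytest.approx(D, abs=1e-9)
        # 6 weeks fully on treatment, then the continuation fraction
        assert spd["sinus_on"] == pytest.approx(42 + cf * (H - D - 42), abs=1e-9)
        assert spd["sinus_off"] == pytest.approx((1 - cf) * (H - D - 42), abs=1e-9)
        for st, v in spd.items():
            if st not in ("waiting", "sinus_on", "sinus_off"):
                assert v == pytest.approx(0.0, abs=1e-12)

    def test_exactly_one_ecv_performed(self, forced_ps):
        totals = _trace(forced_ps, "riva").ledger_totals()
        assert totals["ecv_performed"] == pytest.approx(1.0, abs=1e-12)
        assert totals.get("cancel_last_minute", 0.0) == 0.0
        assert totals.get("cancel_early", 0.0) == 0.0
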