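"""Individual-level Monte-Carlo oracle for the cohort engine.

Simulates n patients through the identical clinical pathway (daily pre-ECV
cycles, attempt splits, weekly post-ECV cycles) by sampling each patient's
transitions rather than propagating expected occupancies.  It reuses the
parameter-to-cycle-probability conversions (via build_model) but implements
the pathway independently of the cohort engine's occupancy arithmetic, so
agreement between the two routes is evidence, not tautology.

Clarity over speed; this is a validation construct, not a performance path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import (LAST_MINUTE_WINDOW_DAYS, ModelSpec, S, build_model)
from .outcomes import NONHEALTH, OutcomeSummary, state_utility_vector
from .params import ParameterSet, pval

__all__ = ["MicrosimResult", "simulate_individuals", "crossvalidate"]

WAITING = -1
CATEGORIES = ("drug", "inr_monitoring", "ecv_procedure", "cancellations",
              "event_care", "productivity_loss", "informal_care")

_LIVE_AF = np.array([S.SINUS_ON, S.SINUS_OFF, S.RECUR_ON, S.RECUR_OFF,
                     S.PERM_ON, S.PERM_OFF])
_ON = np.array([S.SINUS_ON, S.RECUR_ON, S.PERM_ON, S.IS_ON, S.MI_ON,
                S.MAH_ON, S.GIH_ON])
_POST_EVENT = np.array([S.IS_ON, S.IS_OFF, S.MI_ON, S.MI_OFF, S.ICH,
                        S.MAH_ON, S.MAH_OFF, S.GIH_ON, S.GIH_OFF])
_OFF_OF = {S.SINUS_ON: S.SINUS_OFF, S.RECUR_ON: S.RECUR_OFF,
           S.PERM_ON: S.PERM_OFF, S.IS_ON: S.IS_OFF, S.MI_ON: S.MI_OFF,
           S.MAH_ON: S.MAH_OFF, S.GIH_ON: S.GIH_OFF}


@dataclass
class MicrosimResult:
    arm: str
    n: int
    seed: int
    qalys: np.ndarray                     # (n,) per-patient
    costs: dict[str, np.ndarray]          # per-category (n,) arrays (societal)

    def mean_se(self, perspective: str = "societal"
                ) -> tuple[OutcomeSummary, dict[str, float]]:
        """Mean outcome summary and Monte-Carlo SEs of every reported quantity."""
        cats = {c: (np.zeros_like(self.qalys) if (perspective == "payer"
                                                  and c in NONHEALTH) else v)
                for c, v in self.costs.items()}
        total = sum(cats.values())
        mean = OutcomeSummary(arm=self.arm, perspective=perspective,
                              qalys=float(self.qalys.mean()),
                              costs={c: float(v.mean()) for c, v in cats.items()})
        rootn = np.sqrt(self.n)
        se = {c: float(v.std(ddof=1)) / rootn for c, v in cats.items()}
        se["qalys"] = float(self.qalys.std(ddof=1)) / rootn
        se["total_cost"] = float(total.std(ddof=1)) / rootn
        return mean, se


def _per_patient_daily_costs(model: ModelSpec, params: ParameterSet
                             ) -> dict[str, dict[int, float] | float]:
    """Deterministic per-day accrual rates by state (euro/day and QALY/day)."""
    arm = params.arms[model.arm]
    cs = params.costs
    u_vec = state_utility_vector(params)
    drug = pval(arm.drug_cost_per_day)
    blended_unit = (cs.inr_mix_service * pval(cs.inr_unit_service)
                    + cs.inr_mix_home * pval(cs.inr_unit_home))
    inr_pre = cs.inr_pre_ecv_count * blended_unit / model.pre_ecv_days
    inr_year = (cs.inr_mix_service * cs.inr_service_per_year * pval(cs.inr_unit_service)
                + cs.inr_mix_home * cs.inr_home_per_year * pval(cs.inr_unit_home))
    prod = pval(cs.productivity_per_week) / 7.0
    care = pval(cs.informal_unit_per_hour)
    non_h = cs.informal_hours["nonintensive"] * care / 7.0
    int_h = cs.informal_hours["intensive"] * care / 7.0

    weekly = np.zeros(16)
    weekly[[S.IS_ON, S.IS_OFF]] = pval(cs.weekly["is_"])
    weekly[[S.MI_ON, S.MI_OFF]] = pval(cs.weekly["mi"])
    weekly[S.ICH] = pval(cs.weekly["ich"])
    weekly[[S.MAH_ON, S.MAH_OFF]] = pval(cs.weekly["mah"])
    weekly[[S.GIH_ON, S.GIH_OFF]] = pval(cs.weekly["gih"])

    prod_day = np.zeros(16)
    informal_day = np.zeros(16)
    sympt = cs.symptomatic_share_post
    for col in (S.RECUR_ON, S.RECUR_OFF, S.PERM_ON, S.PERM_OFF):
        prod_day[col] = sympt * prod
        informal_day[col] = sympt * non_h
    for col in (S.IS_ON, S.IS_OFF, S.MI_ON, S.MI_OFF, S.ICH):
        prod_day[col] = prod
        informal_day[col] = int_h
    for col in (S.MAH_ON, S.MAH_OFF, S.GIH_ON, S.GIH_OFF):
        prod_day[col] = prod
        informal_day[col] = non_h

    return {"u_vec": u_vec, "drug": drug, "inr_pre": inr_pre,
            "inr_year": inr_year, "prod_wait": cs.symptomatic_share_pre * prod,
            "informal_wait": cs.symptomatic_share_pre * non_h,
            "weekly_state": weekly, "prod_day": prod_day,
            "informal_day": informal_day}


def simulate_individuals(params: ParameterSet, arm: str, n: int,
                         seed: int) -> MicrosimResult:
    """Simulate n individual patients; deterministic given seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    model = build_model(params, arm)
    a = params.arms[arm]
    cs = params.costs
    rates = _per_patient_daily_costs(model, params)
    rng = np.random.default_rng(seed)
    H, D = model.horizon_days, model.pre_ecv_days
    cf = model.continuation
    u_sym = pval(params.utilities.symptomatic_af)
    tariff = pval(cs.ecv_tariff)
    admin = pval(cs.nurse_hourly_wage) * cs.early_cancel_minutes / 60.0
    last_cost = cs.lastminute_factor * tariff
    ssr_cost = last_cost + pval(cs.ssr_consult_cost)
    acute = {ev: pval(cs.acute[ev]) for ev in cs.acute}

    qaly = np.zeros(n)
    cost = {c: np.zeros(n) for c in CATEGORIES}
    state = np.full(n, WAITING, dtype=np.int64)
    entry_day = np.full(n, -1, dtype=np.int64)
    flag6 = np.zeros(n, dtype=bool)

    def enter(mask: np.ndarray, day: int, st_on: int, with_window: bool,
              u_cont: np.ndarray) -> None:
        """Move patients into a post-phase state, applying the continuation
        split at entry unless the 6-week window applies."""
        if with_window:
            state[mask] = st_on
        else:
            cont = u_cont[mask] < cf
            st = np.where(cont, st_on, _OFF_OF.get(st_on, st_on))
            state[mask] = st
        entry_day[mask] = day
        flag6[mask] = with_window

    pre_targets = {"is_": S.IS_ON, "mi": S.MI_ON, "ich": S.ICH,
                   "mah": S.MAH_ON, "gih": S.GIH_ON}
    causes = ["death", "is_", "mi", "ich", "mah", "gih", "ssr"]

    attempt, ecv_day = 1, D
    for d in range(H):
        waiting = state == WAITING
        if not waiting.any():
            break
        if d == ecv_day:
            u = rng.random(n)
            u2 = rng.random(n)
            ucont = rng.random(n)
            p_in = model.p_inadequate[attempt - 1]
            inad = waiting & (u < p_in)
            performed = waiting & ~inad
            cost["cancellations"][inad] += last_cost
            cost["ecv_procedure"][performed] += tariff
            success = performed & (u2 < model.p_success)
            failed = performed & ~success
            enter(success, d, S.SINUS_ON, True, ucont)
            if attempt < model.max_attempts:
                attempt += 1
                ecv_day = d + D
            else:
                enter(inad, d, S.PERM_ON, False, ucont)
                enter(failed, d, S.PERM_ON, True, ucont)
            waiting = state == WAITING
            if not waiting.any():
                break
        # accrue the waiting day (start-of-cycle occupancy)
        qaly[waiting] += u_sym / 365.0
        cost["drug"][waiting] += rates["drug"]
        if a.inr_monitored:
            cost["inr_monitoring"][waiting] += rates["inr_pre"]
        cost["productivity_loss"][waiting] += rates["prod_wait"]
        cost["informal_care"][waiting] += rates["informal_wait"]
        # transient minor hemorrhage (no exclusion from ECV)
        mih = waiting & (rng.random(n) < model.p_day["mih"])
        cost["event_care"][mih] += acute["mih"]
        # competing exclusion events + spontaneous sinus rhythm + death
        qd = float(model.q_day[d])
        probs = np.array([qd] + [model.p_day[ev] for ev in causes[1:-1]]
                         + [model.p_day["ssr"]])
        surv = np.prod(1.0 - probs)
        psum = probs.sum()
        scale = (1.0 - surv) / psum if psum > 0 else 0.0
        edges = np.concatenate([[0.0], np.cumsum(probs * scale)])
        u = rng.random(n)
        ucont = rng.random(n)
        cancel_last = ecv_day - d <= LAST_MINUTE_WINDOW_DAYS
        for j, cause in enumerate(causes):
            hit = waiting & (u >= edges[j]) & (u < edges[j + 1])
            if not hit.any():
                continue
            if cause == "ssr":
                cost["cancellations"][hit] += ssr_cost
                enter(hit, d + 1, S.SINUS_ON, True, ucont)
            elif cause == "death":
                cost["cancellations"][hit] += last_cost if cancel_last else admin
                state[hit] = S.DEAD
            else:
                cost["cancellations"][hit] += last_cost if cancel_last else admin
                cost["event_care"][hit] += acute[cause]
                tgt = pre_targets[cause]
                enter(hit, d + 1, tgt, False, ucont)

    # ----- post phase: weekly cycles from each patient's entry day ----------
    u_vec = rates["u_vec"]
    p_is, p_mi, p_ich = (model.p_week["is_"], model.p_week["mi"],
                         model.p_week["ich"])
    for w in range(int(np.ceil(H / 7)) + 1):
        t = entry_day + 7 * w
        in_post = (state >= 0) & (state != S.DEAD) & (entry_day >= 0)
        active = in_post & (t < H)
        if not active.any():
            break
        if w == model.oac_weeks:
            on = active & flag6 & np.isin(state, _ON)
            stop = on & (rng.random(n) >= cf)
            state[stop] = np.array([_OFF_OF[s] for s in state[stop]]) \
                if stop.any() else state[stop]
        days = np.clip(H - t, 0, 7)
        st = state.copy()
        # accrual in the start-of-week state
        qaly[active] += u_vec[st[active]] * days[active] / 365.0
        on_mask = active & np.isin(st, _ON)
        cost["drug"][on_mask] += rates["drug"] * days[on_mask]
        if a.inr_monitored:
            cost["inr_monitoring"][on_mask] += rates["inr_year"] / 365.0 * days[on_mask]
        cost["event_care"][active] += rates["weekly_state"][st[active]] \
            * days[active] / 7.0
        cost["productivity_loss"][active] += rates["prod_day"][st[active]] * days[active]
        cost["informal_care"][active] += rates["informal_day"][st[active]] * days[active]

        full = active & (days == 7)
        qw = model.q_week[np.clip(t, 0, H - 1)]
        # transient bleeds from live AF/sinus states
        live = full & np.isin(st, _LIVE_AF)
        for ev in ("mah", "gih", "mih"):
            hit = live & (rng.random(n) < model.p_week[ev])
            cost["event_care"][hit] += acute[ev]
        # absorbing events and death, proportional-allocation competing risks
        probs = np.stack([qw, np.full(n, p_is), np.full(n, p_mi),
                          np.full(n, p_ich)])
        surv = np.prod(1.0 - probs, axis=0)
        psum = probs.sum(axis=0)
        scale = np.divide(1.0 - surv, psum, out=np.zeros(n), where=psum > 0)
        edges = np.cumsum(probs * scale, axis=0)
        u = rng.random(n)
        urec = rng.random(n)
        was_on = np.isin(st, np.array([S.SINUS_ON, S.RECUR_ON, S.PERM_ON]))
        hit_death = live & (u < edges[0])
        hit_is = live & (u >= edges[0]) & (u < edges[1])
        hit_mi = live & (u >= edges[1]) & (u < edges[2])
        hit_ich = live & (u >= edges[2]) & (u < edges[3])
        state[hit_death] = S.DEAD
        state[hit_is & was_on] = S.IS_ON
        state[hit_is & ~was_on] = S.IS_OFF
        state[hit_mi & was_on] = S.MI_ON
        state[hit_mi & ~was_on] = S.MI_OFF
        state[hit_ich] = S.ICH
        cost["event_care"][hit_is] += acute["is_"]
        cost["event_care"][hit_mi] += acute["mi"]
        cost["event_care"][hit_ich] += acute["ich"]
        # AF recurrence among event-free sinus-rhythm patients
        survived = live & (u >= edges[3])
        rec = survived & np.isin(st, np.array([S.SINUS_ON, S.SINUS_OFF])) \
            & (urec < model.p_recur_week)
        state[rec & (st == S.SINUS_ON)] = S.RECUR_ON
        state[rec & (st == S.SINUS_OFF)] = S.RECUR_OFF
        # established post-event states: background mortality only
        pe = full & np.isin(st, _POST_EVENT)
        dies = pe & (rng.random(n) < qw)
        state[dies] = S.DEAD

    return MicrosimResult(arm=arm, n=n, seed=seed, qalys=qaly, costs=cost)


def crossvalidate(cohort: OutcomeSummary, micro: MicrosimResult,
                  z: float = 3.0, atol: float = 1e-9) -> pd.DataFrame:
    """Flag every summary quantity where the cohort-model expectation falls
    more than z Monte-Carlo SEs from the micro-simulation mean."""
    if cohort.arm != micro.arm:
        raise ValueError("cohort and micro-simulation results are for "
                         f"different arms ({cohort.arm!r} vs {micro.arm!r})")
    mean, se = micro.mean_se(cohort.perspective)
    rows = []
    quantities = [("qalys", cohort.qalys, mean.qalys, se["qalys"])]
    for c in CATEGORIES:
        quantities.append((c, cohort.costs[c], mean.costs[c], se[c]))
    quantities.append(("total_cost", cohort.total_cost, mean.total_cost,
                       se["total_cost"]))
    for name, expected, observed, s in quantities:
        diff = abs(expected - observed)
        rows.append({"quantity": name, "cohort": expected, "microsim": observed,
                     "se": s, "z": (diff / s if s > 0 else np.inf if diff > atol
                                    else 0.0),
                     "pass": bool(diff <= z * s + atol)})
    return pd.DataFrame(rows)
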