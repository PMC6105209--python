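"""QALY and cost accounting per arm, and the incremental comparison.

Costs are categorized as drug, INR monitoring, ECV procedure, cancellations,
event care, productivity loss and informal care.  The societal perspective
includes all categories; the payer perspective drops the last two.  Neither
costs nor health effects are discounted (1-year horizon).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import S, CohortTrace, NS
from .params import ParameterSet, pval

__all__ = ["OutcomeSummary", "CEResult", "state_utility_vector",
           "accumulate_qalys", "accumulate_costs", "summarize", "compare_arms",
           "results_table"]

PERSPECTIVES = ("societal", "payer")
NONHEALTH = ("productivity_loss", "informal_care")

_ON_COLS = (S.SINUS_ON, S.RECUR_ON, S.PERM_ON, S.IS_ON, S.MI_ON, S.MAH_ON, S.GIH_ON)
_AF_POST_COLS = (S.RECUR_ON, S.RECUR_OFF, S.PERM_ON, S.PERM_OFF)
_INTENSIVE_COLS = (S.IS_ON, S.IS_OFF, S.MI_ON, S.MI_OFF, S.ICH)
_BLEED_STATE_COLS = (S.MAH_ON, S.MAH_OFF, S.GIH_ON, S.GIH_OFF)


@dataclass
class OutcomeSummary:
    arm: str
    perspective: str
    qalys: float
    costs: dict[str, float] = field(default_factory=dict)

    @property
    def total_cost(self) -> float:
        return sum(self.costs.values())


@dataclass
class CEResult:
    delta_cost: float
    delta_qalys: float
    wtp: float
    perspective: str

    @property
    def icer(self) -> float | None:
        """Incremental cost per QALY; None when the QALY difference is zero
        or the comparison is dominance (reported via the label instead)."""
        if self.delta_qalys == 0.0:
            return None
        return self.delta_cost / self.delta_qalys

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qalys - self.delta_cost

    @property
    def dominance(self) -> str:
        dc, dq = self.delta_cost, self.delta_qalys
        if dq > 0 and dc <= 0:
            return "dominant"
        if dq < 0 and dc >= 0:
            return "dominated"
        if dq >= 0 and dc >= 0:
            return "trade-off NE"
        return "trade-off SW"


def state_utility_vector(params: ParameterSet) -> np.ndarray:
    """Utility per post-phase state column (sinus rhythm counts as
    asymptomatic; recurrent AF as symptomatic; death zero)."""
    u = params.utilities
    vec = np.zeros(NS)
    vec[S.SINUS_ON] = vec[S.SINUS_OFF] = pval(u.asymptomatic_af)
    vec[S.RECUR_ON] = vec[S.RECUR_OFF] = pval(u.symptomatic_af)
    vec[S.PERM_ON] = vec[S.PERM_OFF] = pval(u.permanent_af)
    vec[S.IS_ON] = vec[S.IS_OFF] = pval(u.post_is)
    vec[S.MI_ON] = vec[S.MI_OFF] = pval(u.post_mi)
    vec[S.ICH] = pval(u.post_ich)
    vec[S.MAH_ON] = vec[S.MAH_OFF] = pval(u.mah)
    vec[S.GIH_ON] = vec[S.GIH_OFF] = pval(u.gih)
    return vec


def _person_days(trace: CohortTrace) -> np.ndarray:
    """(16,) person-days per post-phase state."""
    return (trace.post_occ * trace.week_days[:, :, None]).sum(axis=(0, 1))


def accumulate_qalys(trace: CohortTrace, params: ParameterSet) -> float:
    """Undiscounted QALYs: sum of occupancy x utility x cycle length in years.
    Minor hemorrhage carries no disutility."""
    u_vec = state_utility_vector(params)
    u_wait = pval(params.utilities.symptomatic_af)
    pdays = _person_days(trace)
    return float((trace.wait.sum() * u_wait + pdays @ u_vec) / 365.0)


def accumulate_costs(trace: CohortTrace, params: ParameterSet,
                     perspective: str) -> dict[str, float]:
    """Per-category euro cost per patient for one arm's trace."""
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    arm = params.arms[trace.arm]
    cs = params.costs
    pdays = _person_days(trace)
    wait_days = float(trace.wait.sum())
    on_days = wait_days + float(pdays[list(_ON_COLS)].sum())
    totals = trace.ledger_totals()

    costs: dict[str, float] = {}
    costs["drug"] = on_days * pval(arm.drug_cost_per_day)

    if arm.inr_monitored:
        blended_unit = (cs.inr_mix_service * pval(cs.inr_unit_service)
                        + cs.inr_mix_home * pval(cs.inr_unit_home))
        pre = wait_days * cs.inr_pre_ecv_count * blended_unit / trace.pre_ecv_days
        annual = (cs.inr_mix_service * cs.inr_service_per_year * pval(cs.inr_unit_service)
                  + cs.inr_mix_home * cs.inr_home_per_year * pval(cs.inr_unit_home))
        periodic = float(pdays[list(_ON_COLS)].sum()) * annual / 365.0
        costs["inr_monitoring"] = pre + periodic
    else:
        costs["inr_monitoring"] = 0.0

    tariff = pval(cs.ecv_tariff)
    costs["ecv_procedure"] = totals.get("ecv_performed", 0.0) * tariff
    admin = pval(cs.nurse_hourly_wage) * cs.early_cancel_minutes / 60.0
    costs["cancellations"] = (
        totals.get("cancel_last_minute", 0.0) * cs.lastminute_factor * tariff
        + totals.get("cancel_early", 0.0) * admin
        + totals.get("cancel_ssr", 0.0) * (cs.lastminute_factor * tariff
                                           + pval(cs.ssr_consult_cost)))

    event_care = 0.0
    for ev in ("is_", "mi", "ich", "mah", "gih", "mih"):
        event_care += totals.get("ev_" + ev, 0.0) * pval(cs.acute[ev])
    weekly_days = {"is_": pdays[S.IS_ON] + pdays[S.IS_OFF],
                   "mi": pdays[S.MI_ON] + pdays[S.MI_OFF],
                   "ich": pdays[S.ICH],
                   "mah": pdays[S.MAH_ON] + pdays[S.MAH_OFF],
                   "gih": pdays[S.GIH_ON] + pdays[S.GIH_OFF]}
    for ev, d in weekly_days.items():
        event_care += float(d) * pval(cs.weekly[ev]) / 7.0
    costs["event_care"] = event_care

    # non-health-care categories accrue on the symptomatic share of AF mass
    # (70% pre-ECV, 32% post-ECV) and on the post-event states
    af_post_days = float(pdays[list(_AF_POST_COLS)].sum())
    intensive_days = float(pdays[list(_INTENSIVE_COLS)].sum())
    bleed_days = float(pdays[list(_BLEED_STATE_COLS)].sum())
    sympt_days = (cs.symptomatic_share_pre * wait_days
                  + cs.symptomatic_share_post * af_post_days)
    prod_week = pval(cs.productivity_per_week)
    costs["productivity_loss"] = (sympt_days + intensive_days + bleed_days) \
        * prod_week / 7.0
    unit = pval(cs.informal_unit_per_hour)
    costs["informal_care"] = (
        (sympt_days + bleed_days) * cs.informal_hours["nonintensive"] * unit / 7.0
        + intensive_days * cs.informal_hours["intensive"] * unit / 7.0)

    if perspective == "payer":
        for cat in NONHEALTH:
            costs[cat] = 0.0
    return costs


def summarize(trace: CohortTrace, params: ParameterSet,
              perspective: str) -> OutcomeSummary:
    return OutcomeSummary(arm=trace.arm, perspective=perspective,
                          qalys=accumulate_qalys(trace, params),
                          costs=accumulate_costs(trace, params, perspective))


def compare_arms(out_riva: OutcomeSummary, out_vka: OutcomeSummary,
                 wtp: float) -> CEResult:
    """Incremental comparison (rivaroxaban minus VKA) on unrounded values."""
    if out_riva.perspective != out_vka.perspective:
        raise ValueError("cannot compare summaries from different perspectives")
    return CEResult(delta_cost=out_riva.total_cost - out_vka.total_cost,
                    delta_qalys=out_riva.qalys - out_vka.qalys,
                    wtp=wtp, perspective=out_riva.perspective)


def results_table(summaries: dict[str, dict[str, OutcomeSummary]],
                  wtp: float) -> pd.DataFrame:
    """Headline table: per-arm cost and QALYs plus the increments and ICER,
    one block per perspective."""
    rows = []
    for persp, by_arm in summaries.items():
        ce = compare_arms(by_arm["riva"], by_arm["vka"], wtp)
        icer = ce.icer
        for arm in ("riva", "vka"):
            s = by_arm[arm]
            rows.append({"perspective": persp, "arm": arm,
                         "cost_per_patient": s.total_cost, "qalys": s.qalys,
                         "delta_cost": ce.delta_cost if arm == "riva" else math.nan,
                         "delta_qalys": ce.delta_qalys if arm == "riva" else math.nan,
                         "icer": (icer if (arm == "riva" and icer is not None)
                                  else math.nan),
                         "dominance": ce.dominance if arm == "riva" else ""})
    return pd.DataFrame(rows)
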