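"""Two-phase Markov cohort engine.

Phase 1 (daily cycles): the cohort waits on anticoagulation for its scheduled
electrical cardioversion (ECV), exposed each day to ischemic stroke (IS),
myocardial infarction (MI), intracranial hemorrhage (ICH), major and
gastrointestinal hemorrhage (MaH/GIH, absorbing before ECV), minor hemorrhage
(MiH, transient), spontaneous sinus rhythm (SSR) and background death.  Any
clinical event or SSR cancels the procedure.  On the scheduled day the waiting
mass splits into inadequately anticoagulated (last-minute cancellation,
rescheduled once), performed-and-successful (sinus rhythm) and
performed-but-failed (rescheduled once).  After two unsuccessful or cancelled
attempts patients have permanent AF.

Phase 2 (weekly cycles to the 1-year horizon): sinus-rhythm patients stay on
anticoagulation for 6 weeks, then only the stroke-risk-eligible fraction
continues; AF can recur; IS/MI/ICH absorb (ICH stops anticoagulation); MaH/GIH
become transient (cost, return to the originating state); background mortality
is age-specific and advances with calendar time.

Competing risks within a cycle use the joint-survivor rule: survival
S = prod(1 - p_i), total event mass 1 - S allocated proportionally to p_i.
The final cycle truncated by the horizon accrues time pro rata but applies no
transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import ParameterSet, annual_to_cycle, annual_prob_to_cycle_prob, pval

__all__ = [
    "POST_STATES", "S", "ModelSpec", "CohortTrace",
    "build_model", "run_cohort",
    "pre_ecv_daily_step", "ecv_attempt_split", "post_ecv_weekly_step",
]

POST_STATES = ("sinus_on", "sinus_off", "recur_on", "recur_off", "perm_on",
               "perm_off", "is_on", "is_off", "mi_on", "mi_off", "ich",
               "mah_on", "mah_off", "gih_on", "gih_off", "dead")


class S:
    """Column indices of the post-phase occupancy vector."""
    SINUS_ON, SINUS_OFF, RECUR_ON, RECUR_OFF, PERM_ON, PERM_OFF, \
        IS_ON, IS_OFF, MI_ON, MI_OFF, ICH, MAH_ON, MAH_OFF, GIH_ON, GIH_OFF, \
        DEAD = range(16)


NS = 16
ON_STATES = (S.SINUS_ON, S.RECUR_ON, S.PERM_ON, S.IS_ON, S.MI_ON, S.MAH_ON, S.GIH_ON)
OFF_OF = {S.SINUS_ON: S.SINUS_OFF, S.RECUR_ON: S.RECUR_OFF, S.PERM_ON: S.PERM_OFF,
          S.IS_ON: S.IS_OFF, S.MI_ON: S.MI_OFF, S.MAH_ON: S.MAH_OFF,
          S.GIH_ON: S.GIH_OFF}
AF_LIVE = (S.SINUS_ON, S.SINUS_OFF, S.RECUR_ON, S.RECUR_OFF, S.PERM_ON, S.PERM_OFF)
POST_EVENT = (S.IS_ON, S.IS_OFF, S.MI_ON, S.MI_OFF, S.ICH,
              S.MAH_ON, S.MAH_OFF, S.GIH_ON, S.GIH_OFF)

PRE_EVENTS = ("is_", "mi", "ich", "mah", "gih")  # exclusion events before ECV
LAST_MINUTE_WINDOW_DAYS = 2                      # <=48 h before the procedure


@dataclass
class ModelSpec:
    """Precomputed per-cycle transition inputs for one arm."""
    arm: str
    pre_ecv_days: int
    horizon_days: int
    max_attempts: int
    oac_weeks: int
    continuation: float
    start_age: float
    p_success: float
    p_inadequate: tuple[float, float]       # (first attempt, second attempt)
    p_day: dict[str, float]                 # daily pre-ECV event probabilities
    p_week: dict[str, float]                # weekly post-ECV event probabilities
    p_recur_week: float
    q_day: np.ndarray                       # (H,) daily background death prob
    q_week: np.ndarray                      # (H,) weekly death prob at day index


def _mortality_by_day(params: ParameterSet, horizon: int) -> np.ndarray:
    table = params.events.mortality
    ages = np.array([a for a, _ in table])
    qs = np.array([q for _, q in table])
    day_ages = params.cohort.start_age + np.arange(horizon) / 365.0
    idx = np.clip(np.searchsorted(ages, day_ages, side="right") - 1, 0, len(qs) - 1)
    return qs[idx]


def build_model(params: ParameterSet, arm: str) -> ModelSpec:
    """Expand a validated ParameterSet into per-cycle inputs for one arm."""
    if arm not in params.arms:
        raise ValueError(f"unknown arm {arm!r}")
    a = params.arms[arm]
    horizon = params.schedule.horizon_weeks * 7
    if a.pre_ecv_days * params.schedule.max_attempts >= horizon:
        raise ValueError(
            f"horizon of {horizon} days is shorter than the scheduled "
            f"pre-ECV waits ({params.schedule.max_attempts} x {a.pre_ecv_days} days)")

    p_day = {ev: annual_to_cycle(pval(getattr(params.events, ev).value),
                                 getattr(params.events, ev).kind, 1)
             for ev in ("is_", "mi", "ich", "mah", "gih", "mih")}
    p_day["ssr"] = annual_prob_to_cycle_prob(pval(params.ecv.ssr_annual_prob), 1)
    p_week = {ev: annual_to_cycle(pval(getattr(params.events, ev).value),
                                  getattr(params.events, ev).kind, 7)
              for ev in ("is_", "mi", "ich", "mah", "gih", "mih")}

    q_annual = _mortality_by_day(params, horizon)
    q_day = 1.0 - (1.0 - q_annual) ** (1.0 / 365.0)
    q_week = 1.0 - (1.0 - q_annual) ** (7.0 / 365.0)

    daily_total = sum(p_day[ev] for ev in PRE_EVENTS) + p_day["ssr"] + q_day.max()
    if daily_total > 1.0:
        raise ValueError("daily pre-ECV event probabilities sum above 1")

    return ModelSpec(
        arm=arm, pre_ecv_days=a.pre_ecv_days, horizon_days=horizon,
        max_attempts=params.schedule.max_attempts,
        oac_weeks=params.schedule.post_ecv_oac_weeks,
        continuation=params.continuation_fraction(),
        start_age=params.cohort.start_age,
        p_success=pval(params.ecv.p_success),
        p_inadequate=(pval(a.p_inadequate_first), pval(a.p_inadequate_second)),
        p_day=p_day, p_week=p_week,
        p_recur_week=annual_prob_to_cycle_prob(
            pval(params.ecv.recurrence_annual_prob), 7),
        q_day=q_day, q_week=q_week)


# ---------------------------------------------------------------------------
# Single-cycle operations
# ---------------------------------------------------------------------------

def pre_ecv_daily_step(mass_waiting: float, day: int, model: ModelSpec,
                       ) -> tuple[float, dict[str, float]]:
    """One daily cycle for the waiting mass.

    Returns the surviving waiting mass and the exit masses keyed by cause
    ('death', 'is_', 'mi', 'ich', 'mah', 'gih', 'ssr') plus the transient
    'mih' flow (which does not leave the waiting state).
    """
    qd = float(model.q_day[min(day, model.horizon_days - 1)])
    causes = [("death", qd)] + [(ev, model.p_day[ev]) for ev in PRE_EVENTS] \
        + [("ssr", model.p_day["ssr"])]
    surv = 1.0
    for _, p in causes:
        surv *= 1.0 - p
    psum = sum(p for _, p in causes)
    frac = (1.0 - surv) / psum if psum > 0 else 0.0
    exits = {name: mass_waiting * p * frac for name, p in causes}
    exits["mih"] = mass_waiting * model.p_day["mih"]
    return mass_waiting * surv, exits


def ecv_attempt_split(mass_waiting: float, attempt: int, model: ModelSpec,
                      ) -> dict[str, float]:
    """Split the waiting mass on the scheduled ECV day.

    Inadequately anticoagulated patients are cancelled last-minute; the rest
    undergo the procedure and either convert to sinus rhythm or fail.
    """
    if not (1 <= attempt <= model.max_attempts):
        raise ValueError(f"attempt {attempt} exceeds the cap of {model.max_attempts}")
    p_in = model.p_inadequate[attempt - 1]
    inadequate = mass_waiting * p_in
    performed = mass_waiting - inadequate
    success = performed * model.p_success
    return {"inadequate": inadequate, "performed": performed,
            "success": success, "failed": performed - success}


def post_ecv_weekly_step(occ: np.ndarray, q_week: np.ndarray, model: ModelSpec,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """One weekly cycle on (n_cohorts, 16) occupancy.

    Returns (new occupancy, incidence flows (n_cohorts, 6) ordered
    MaH, GIH, MiH (transient) then IS, MI, ICH (absorbing)).
    ``q_week`` is the per-cohort weekly death probability for this cycle.
    """
    p_is, p_mi, p_ich = (model.p_week["is_"], model.p_week["mi"],
                         model.p_week["ich"])
    qd = np.asarray(q_week, dtype=float)
    surv = (1.0 - qd) * (1.0 - p_is) * (1.0 - p_mi) * (1.0 - p_ich)
    psum = qd + p_is + p_mi + p_ich
    frac = np.divide(1.0 - surv, psum, out=np.zeros_like(qd), where=psum > 0)
    a_death, a_is, a_mi, a_ich = qd * frac, p_is * frac, p_mi * frac, p_ich * frac

    new = occ.copy()
    for col in AF_LIVE:
        m = occ[:, col]
        on = col in (S.SINUS_ON, S.RECUR_ON, S.PERM_ON)
        new[:, col] -= m * (1.0 - surv)
        new[:, S.DEAD] += m * a_death
        new[:, S.IS_ON if on else S.IS_OFF] += m * a_is
        new[:, S.MI_ON if on else S.MI_OFF] += m * a_mi
        new[:, S.ICH] += m * a_ich  # anticoagulation is discontinued after ICH
    # AF recurrence among sinus-rhythm survivors
    for src, dst in ((S.SINUS_ON, S.RECUR_ON), (S.SINUS_OFF, S.RECUR_OFF)):
        rec = occ[:, src] * surv * model.p_recur_week
        new[:, src] -= rec
        new[:, dst] += rec
    # established post-event states: background mortality only
    for col in POST_EVENT:
        d = occ[:, col] * qd
        new[:, col] -= d
        new[:, S.DEAD] += d
    # event-incidence flows for costing: transient bleeds (MaH/GIH/MiH, from
    # live mass, returning to origin) and new absorbing IS/MI/ICH cases
    live = occ[:, list(AF_LIVE)].sum(axis=1)
    flows = np.stack([live * model.p_week["mah"], live * model.p_week["gih"],
                      live * model.p_week["mih"],
                      live * a_is, live * a_mi, live * a_ich], axis=1)
    return new, flows


def _apply_continuation_split(occ: np.ndarray, rows: np.ndarray, cf: float) -> None:
    """Move (1-cf) of each on-anticoagulant state to its off counterpart."""
    for on_col in ON_STATES:
        moved = occ[rows, on_col] * (1.0 - cf)
        occ[rows, on_col] -= moved
        occ[rows, OFF_OF[on_col]] += moved


# ---------------------------------------------------------------------------
# Cohort trace
# ---------------------------------------------------------------------------

@dataclass
class CohortTrace:
    """Occupancy and event flows for one arm over the model horizon."""
    arm: str
    horizon_days: int
    pre_ecv_days: int
    wait: np.ndarray                    # (H,) waiting mass, start of day
    dead_pre: np.ndarray                # (H,) cumulative pre-phase deaths
    entry_days: np.ndarray              # (n,) post-phase cohort entry days
    week6_flags: np.ndarray             # (n,) bool: 6-week OAC window applies
    post_occ: np.ndarray                # (n, W, 16)
    week_days: np.ndarray               # (n, W) days each local week accrues
    post_flows: np.ndarray              # (n, W, 3) MaH, GIH, MiH flows
    pre_ledger: dict[tuple[int, str], float] = field(default_factory=dict)

    def daily_occupancy(self) -> np.ndarray:
        """(H, 17) matrix: waiting column followed by the 16 post-phase states,
        with pre-phase deaths folded into the dead column."""
        H = self.horizon_days
        out = np.zeros((H, NS + 1))
        out[:, 0] = self.wait
        out[:, 1 + S.DEAD] += self.dead_pre
        for i, e in enumerate(self.entry_days):
            for w in range(self.post_occ.shape[1]):
                lo = int(e) + 7 * w
                if lo >= H:
                    break
                hi = min(lo + 7, H)
                out[lo:hi, 1:] += self.post_occ[i, w]
        return out

    def ledger_frame(self) -> pd.DataFrame:
        """Tidy event ledger: day, event code, cohort mass."""
        rows = [(d, code, m) for (d, code), m in sorted(self.pre_ledger.items())]
        codes = ("ev_mah", "ev_gih", "ev_mih", "ev_is_", "ev_mi", "ev_ich")
        for i, e in enumerate(self.entry_days):
            for w in range(self.post_flows.shape[1]):
                day = int(e) + 7 * w
                for j, code in enumerate(codes):
                    m = self.post_flows[i, w, j]
                    if m > 0:
                        rows.append((day, code, m))
        df = pd.DataFrame(rows, columns=["day", "event", "mass"])
        return df.groupby(["day", "event"], as_index=False)["mass"].sum()

    def ledger_totals(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for (_, code), m in self.pre_ledger.items():
            totals[code] = totals.get(code, 0.0) + m
        for j, code in enumerate(("ev_mah", "ev_gih", "ev_mih",
                                  "ev_is_", "ev_mi", "ev_ich")):
            totals[code] = totals.get(code, 0.0) + float(self.post_flows[:, :, j].sum())
        return totals

    def state_person_days(self) -> dict[str, float]:
        """Person-days by state over the horizon (unit cohort)."""
        out = {"waiting": float(self.wait.sum())}
        pd_by_state = (self.post_occ * self.week_days[:, :, None]).sum(axis=(0, 1))
        for k, name in enumerate(POST_STATES):
            out[name] = float(pd_by_state[k])
        return out

    def to_tidy(self) -> pd.DataFrame:
        occ = self.daily_occupancy()
        names = ("waiting",) + POST_STATES
        recs = [(d, names[j], occ[d, j]) for d in range(self.horizon_days)
                for j in range(occ.shape[1]) if occ[d, j] > 0]
        return pd.DataFrame(recs, columns=["day", "state", "occupancy"])


def _ledger_add(ledger: dict, day: int, code: str, mass: float) -> None:
    if mass > 0:
        ledger[(day, code)] = ledger.get((day, code), 0.0) + mass


def run_cohort(model: ModelSpec) -> CohortTrace:
    """Run the full two-phase cohort model for one arm (unit cohort mass)."""
    H, D = model.horizon_days, model.pre_ecv_days
    cf = model.continuation
    wait = np.zeros(H)
    dead_delta = np.zeros(H + 1)
    ledger: dict[tuple[int, str], float] = {}
    entries: dict[tuple[int, bool], np.ndarray] = {}

    def add_entry(day: int, flag: bool, state: int, mass: float) -> None:
        if mass <= 0 or day >= H:
            return
        vec = entries.setdefault((day, flag), np.zeros(NS))
        vec[state] += mass

    def add_split_entry(day: int, state_on: int, mass: float) -> None:
        # continuation rule applied at entry (no 6-week full-OAC window)
        add_entry(day, False, state_on, mass * cf)
        add_entry(day, False, OFF_OF[state_on], mass * (1.0 - cf))

    pre_event_target = {"is_": S.IS_ON, "mi": S.MI_ON, "mah": S.MAH_ON,
                        "gih": S.GIH_ON}

    mass_wait, attempt, ecv_day = 1.0, 1, D
    for d in range(H):
        if d == ecv_day:
            split = ecv_attempt_split(mass_wait, attempt, model)
            _ledger_add(ledger, d, "cancel_last_minute", split["inadequate"])
            _ledger_add(ledger, d, "ecv_performed", split["performed"])
            add_entry(d, True, S.SINUS_ON, split["success"])
            if attempt < model.max_attempts:
                mass_wait = split["inadequate"] + split["failed"]
                attempt += 1
                ecv_day = d + D
            else:
                add_split_entry(d, S.PERM_ON, split["inadequate"])
                # a performed ECV carries the 6-week anticoagulation window
                add_entry(d, True, S.PERM_ON, split["failed"])
                mass_wait = 0.0
            if mass_wait <= 0:
                break
        wait[d] = mass_wait
        mass_wait, exits = pre_ecv_daily_step(mass_wait, d, model)
        _ledger_add(ledger, d, "ev_mih", exits["mih"])
        cancel_code = ("cancel_last_minute"
                       if ecv_day - d <= LAST_MINUTE_WINDOW_DAYS else "cancel_early")
        for ev in PRE_EVENTS:
            m = exits[ev]
            if m <= 0:
                continue
            _ledger_add(ledger, d, "ev_" + ev, m)
            _ledger_add(ledger, d, cancel_code, m)
            if ev == "ich":
                add_entry(d + 1, False, S.ICH, m)
            else:
                add_split_entry(d + 1, pre_event_target[ev], m)
        _ledger_add(ledger, d, cancel_code, exits["death"])
        dead_delta[min(d + 1, H)] += exits["death"]
        _ledger_add(ledger, d, "cancel_ssr", exits["ssr"])
        add_entry(d + 1, True, S.SINUS_ON, exits["ssr"])

    dead_pre = np.cumsum(dead_delta[:H])

    # --- post phase: all entry cohorts stepped weekly in lockstep -----------
    keys = sorted(entries)
    n = len(keys)
    entry_days = np.array([k[0] for k in keys], dtype=int)
    flags = np.array([k[1] for k in keys], dtype=bool)
    if n:
        W = int(np.ceil((H - entry_days.min()) / 7))
    else:
        W = 0
    occ = np.zeros((n, NS))
    for i, k in enumerate(keys):
        occ[i] = entries[k]
    post_occ = np.zeros((n, W, NS))
    post_flows = np.zeros((n, W, 6))
    week_days = np.clip(H - entry_days[:, None] - 7 * np.arange(W)[None, :], 0, 7) \
        if n else np.zeros((0, 0))

    for w in range(W):
        if w == model.oac_weeks and flags.any():
            _apply_continuation_split(occ, np.where(flags)[0], cf)
        post_occ[:, w, :] = occ
        t = entry_days + 7 * w
        full = (H - t) >= 7
        if not full.any():
            break
        qw = model.q_week[np.clip(t, 0, H - 1)]
        stepped, flows = post_ecv_weekly_step(occ, qw, model)
        occ = np.where(full[:, None], stepped, occ)
        post_flows[:, w, :] = np.where(full[:, None], flows, 0.0)

    return CohortTrace(arm=model.arm, horizon_days=H, pre_ecv_days=D,
                       wait=wait, dead_pre=dead_pre,
                       entry_days=entry_days, week6_flags=flags,
                       post_occ=post_occ,
                       week_days=week_days.astype(float),
                       post_flows=post_flows, pre_ledger=ledger)
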