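"""Model inputs: types, validation, and the standard health-economic conversions.

The model compares two anticoagulation strategies (rivaroxaban vs a vitamin K
antagonist, VKA) around elective electrical cardioversion (ECV) of atrial
fibrillation.  Every scalar input may carry parametric uncertainty
(mean + standard error with a beta, gamma or fixed family) for probabilistic
sensitivity analysis; event inputs may be given either as annual incidence
rates (events/person-year) or as annual probabilities.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "UncertainParameter",
    "ValidationError",
    "CohortProfile",
    "SchedulePolicy",
    "ArmParameters",
    "EcvParameters",
    "EventInput",
    "EventRates",
    "UtilitySet",
    "CostSet",
    "MehraDistribution",
    "DemographicsBand",
    "ParameterSet",
    "annual_rate_to_cycle_prob",
    "annual_prob_to_cycle_prob",
    "beta_from_mean_se",
    "gamma_from_mean_se",
    "default_se",
    "continuation_fraction",
    "pval",
    "load_parameter_set",
    "base_case_parameters",
    "save_parameter_set",
    "parameter_set_from_dict",
    "parameter_set_to_dict",
    "validation_report",
]

DEFAULT_WTP = 20_000.0  # euro per QALY gained
DAYS_PER_YEAR = 365.0

EVENT_NAMES = ("is_", "mi", "ich", "mah", "gih", "mih")


class ValidationError(ValueError):
    """Raised when a parameter set violates one of its invariants."""


# ---------------------------------------------------------------------------
# Uncertain scalars
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UncertainParameter:
    """A scalar input with sampling uncertainty.

    family 'beta' requires 0 <= mean <= 1 and feasible moments
    (se^2 < mean*(1-mean)); 'gamma' requires mean > 0; 'fixed' ignores se
    (drug costs and indirect costs are held at fixed prices).
    """

    mean: float
    se: float = 0.0
    family: str = "fixed"
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"unknown distribution family {self.family!r}")
        if self.se < 0:
            raise ValidationError("standard error must be >= 0")
        if self.family == "beta":
            if not (0.0 <= self.mean <= 1.0):
                raise ValidationError(
                    f"beta-family mean must lie in [0, 1], got {self.mean}")
            if self.se > 0 and self.se ** 2 >= self.mean * (1.0 - self.mean):
                raise ValidationError(
                    f"infeasible beta moments: se^2={self.se**2:.6g} >= "
                    f"mean*(1-mean)={self.mean*(1-self.mean):.6g}")
        if self.family == "gamma" and self.mean <= 0:
            raise ValidationError("gamma-family mean must be > 0")


def pval(x: float | UncertainParameter) -> float:
    """Point value of a possibly-uncertain parameter."""
    return x.mean if isinstance(x, UncertainParameter) else float(x)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def annual_rate_to_cycle_prob(rate: float, cycle_days: float) -> float:
    """Convert a constant annual incidence rate to a per-cycle probability.

    Standard exponential conversion 1 - exp(-rate * t) with t in years.
    """
    if rate < 0:
        raise ValueError(f"rate must be >= 0, got {rate}")
    if cycle_days < 1:
        raise ValueError("cycle length must be at least one day")
    return -math.expm1(-rate * cycle_days / DAYS_PER_YEAR)


def annual_prob_to_cycle_prob(p_annual: float, cycle_days: float) -> float:
    """Convert an annual probability to a per-cycle probability
    assuming a constant underlying hazard: 1 - (1-p)^(t/365)."""
    if not (0.0 <= p_annual <= 1.0):
        raise ValueError(f"annual probability must be in [0, 1], got {p_annual}")
    if cycle_days < 1:
        raise ValueError("cycle length must be at least one day")
    if p_annual == 1.0:
        return 1.0
    return -math.expm1(math.log1p(-p_annual) * cycle_days / DAYS_PER_YEAR)


def annual_to_cycle(value: float, kind: str, cycle_days: float) -> float:
    """Dispatch on the declared input kind ('rate' or 'prob')."""
    if kind == "rate":
        return annual_rate_to_cycle_prob(value, cycle_days)
    if kind == "prob":
        return annual_prob_to_cycle_prob(value, cycle_days)
    raise ValueError(f"unknown event input kind {kind!r}")


def beta_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments beta parameters (alpha, beta) for given mean and SE."""
    if not (0.0 < mean < 1.0):
        raise ValueError(f"beta mean must lie strictly in (0, 1), got {mean}")
    var = se * se
    if var <= 0 or var >= mean * (1.0 - mean):
        raise ValueError(
            f"infeasible beta moments: need 0 < se^2 < mean*(1-mean), "
            f"got se^2={var:.6g}, mean*(1-mean)={mean*(1-mean):.6g}")
    nu = mean * (1.0 - mean) / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_mean_se(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments gamma parameters (shape, scale) for given mean and SE."""
    if mean <= 0:
        raise ValueError(f"gamma mean must be > 0, got {mean}")
    if se <= 0:
        raise ValueError(
            "a zero standard error gives a degenerate gamma; use family='fixed'")
    return (mean / se) ** 2, se * se / mean


def default_se(parameter: UncertainParameter, fraction: float = 0.15) -> UncertainParameter:
    """Fill in an assumed standard error as a fraction of the mean.

    Used where no confidence interval is available; the conventional
    assumption is 10-20% of the mean (default: the 15% midpoint).
    """
    if not (0.10 <= fraction <= 0.20):
        raise ValueError(f"assumed-SE fraction must lie in [0.10, 0.20], got {fraction}")
    if parameter.se != 0.0:
        raise ValueError("parameter already has a standard error set")
    return replace(parameter, se=fraction * abs(parameter.mean))


def continuation_fraction(male_share: float, p_score_lt1: float,
                          p_score_lt2: float) -> float:
    """Fraction of the cohort continuing anticoagulation after the 6-week
    post-ECV window: men with CHA2DS2-VASc >= 1 and women with >= 2."""
    for name, v in (("male_share", male_share), ("p_score_lt1", p_score_lt1),
                    ("p_score_lt2", p_score_lt2)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
    if p_score_lt1 > p_score_lt2 + 1e-12:
        raise ValueError("p_score_lt1 cannot exceed p_score_lt2")
    return 1.0 - (male_share * p_score_lt1 + (1.0 - male_share) * p_score_lt2)


# ---------------------------------------------------------------------------
# Structured inputs
# ---------------------------------------------------------------------------

@dataclass
class CohortProfile:
    start_age: float = 64.4
    male_share: float | UncertainParameter = 0.74
    p_score_lt1: float = 0.026   # CHA2DS2-VASc < 1
    p_score_lt2: float = 0.127   # CHA2DS2-VASc < 2
    cohort_size: int = 10_000    # reporting only; the engine is proportion-based


@dataclass
class SchedulePolicy:
    max_attempts: int = 2
    post_ecv_oac_weeks: int = 6
    horizon_weeks: int = 52


@dataclass
class ArmParameters:
    """Inputs that differ between the anticoagulation strategies."""
    pre_ecv_days: int
    p_inadequate_first: float | UncertainParameter
    p_inadequate_second: float | UncertainParameter
    drug_cost_per_day: float | UncertainParameter
    inr_monitored: bool


@dataclass
class EcvParameters:
    p_success: float | UncertainParameter = 0.864
    ssr_annual_prob: float | UncertainParameter = 0.30
    recurrence_annual_prob: float | UncertainParameter = 0.50


@dataclass
class EventInput:
    """An annual clinical-event input, declared as a rate or a probability."""
    value: float | UncertainParameter
    kind: str = "prob"  # 'prob' (annual probability) or 'rate' (events/p-y)


@dataclass
class EventRates:
    """Annual event inputs, identical in both arms in the base case,
    plus the age-specific background mortality table."""
    is_: EventInput
    mi: EventInput
    ich: EventInput
    mah: EventInput
    gih: EventInput
    mih: EventInput
    mortality: list[tuple[float, float]] = field(default_factory=list)  # (age, annual death prob)

    def mortality_annual_prob(self, age: float) -> float:
        """Step-function lookup: the band whose lower age bound is the largest
        one not exceeding `age`; the first band extends downward, the last up."""
        if not self.mortality:
            raise ValidationError("mortality table is empty")
        q = self.mortality[0][1]
        for a, p in self.mortality:
            if age >= a:
                q = p
            else:
                break
        return q


@dataclass
class MehraDistribution:
    """Modified EHRA symptom-class mix and per-class utilities, used to derive
    the AF-state utilities as weighted averages."""
    class_labels: tuple[str, ...] = ("1", "2a", "2b", "3", "4")
    weights: dict[str, float] = field(default_factory=dict)
    utilities: dict[str, float] = field(default_factory=dict)


@dataclass
class UtilitySet:
    symptomatic_af: float | UncertainParameter
    asymptomatic_af: float | UncertainParameter
    permanent_af: float | UncertainParameter
    post_is: float | UncertainParameter
    post_mi: float | UncertainParameter
    post_ich: float | UncertainParameter
    mah: float | UncertainParameter
    gih: float | UncertainParameter
    mih_disutility: float = 0.0  # minor hemorrhage has no disutility
    mehra: MehraDistribution | None = None


@dataclass
class DemographicsBand:
    age_lo: float
    age_hi: float
    participation: float       # labour-market participation, proportion
    hours_per_week: float
    gross_monthly_salary: float


@dataclass
class CostSet:
    # anticoagulation
    inr_unit_service: float | UncertainParameter = 0.0  # euro per measurement
    inr_unit_home: float | UncertainParameter = 0.0
    inr_mix_service: float = 0.569
    inr_mix_home: float = 0.431
    inr_pre_ecv_count: float = 5.5        # measurements before an ECV
    inr_service_per_year: float = 21.1
    inr_home_per_year: float = 23.5
    # procedure
    ecv_tariff: float | UncertainParameter = 0.0
    lastminute_factor: float = 0.5        # <=48 h cancellation: half the tariff
    nurse_hourly_wage: float | UncertainParameter = 0.0
    early_cancel_minutes: float = 30.0    # administrative work on early cancellation
    ssr_consult_cost: float | UncertainParameter = 0.0
    # clinical events (euro): acute on incidence, weekly on post-event occupancy
    acute: dict[str, float | UncertainParameter] = field(default_factory=dict)
    weekly: dict[str, float | UncertainParameter] = field(default_factory=dict)
    # non-health-care
    productivity_per_week: float | UncertainParameter = 0.0
    informal_unit_per_hour: float | UncertainParameter = 0.0
    informal_hours: dict[str, float] = field(
        default_factory=lambda: {"nonintensive": 8.0, "intensive": 26.0})
    symptomatic_share_pre: float = 0.70
    symptomatic_share_post: float = 0.32


@dataclass
class ParameterSet:
    """The complete model input set (the in-silico supplementary input table)."""
    cohort: CohortProfile
    schedule: SchedulePolicy
    arms: dict[str, ArmParameters]          # keys 'riva', 'vka'
    ecv: EcvParameters
    events: EventRates
    utilities: UtilitySet
    costs: CostSet
    wtp: float = DEFAULT_WTP
    demographics: list[DemographicsBand] = field(default_factory=list)
    age_sd: float = 10.8
    metadata: dict[str, Any] = field(default_factory=dict)

    def validate(self) -> None:
        problems = [line for ok, line in _checks(self) if not ok]
        if problems:
            raise ValidationError("; ".join(problems))

    def continuation_fraction(self) -> float:
        return continuation_fraction(pval(self.cohort.male_share),
                                     self.cohort.p_score_lt1,
                                     self.cohort.p_score_lt2)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _prob_ok(x: float) -> bool:
    return 0.0 <= x <= 1.0


def _checks(ps: ParameterSet) -> list[tuple[bool, str]]:
    c: list[tuple[bool, str]] = []

    def add(ok: bool, msg: str) -> None:
        c.append((bool(ok), msg))

    co = ps.cohort
    add(co.start_age > 0, "cohort.start_age must be positive")
    add(_prob_ok(pval(co.male_share)), "cohort.male_share must be in [0,1]")
    add(_prob_ok(co.p_score_lt1), "cohort.p_score_lt1 must be in [0,1]")
    add(_prob_ok(co.p_score_lt2), "cohort.p_score_lt2 must be in [0,1]")
    add(co.p_score_lt1 <= co.p_score_lt2 + 1e-12,
        "cohort.p_score_lt1 must not exceed p_score_lt2")

    add(ps.schedule.max_attempts >= 1, "schedule.max_attempts must be >= 1")
    add(ps.schedule.horizon_weeks >= 1, "schedule.horizon_weeks must be >= 1")
    add(ps.schedule.post_ecv_oac_weeks >= 0,
        "schedule.post_ecv_oac_weeks must be >= 0")

    add(set(ps.arms) == {"riva", "vka"}, "arms must have exactly 'riva' and 'vka'")
    horizon_days = ps.schedule.horizon_weeks * 7
    for name, arm in ps.arms.items():
        add(arm.pre_ecv_days >= 1, f"arms.{name}.pre_ecv_days must be >= 1")
        add(arm.pre_ecv_days * ps.schedule.max_attempts < horizon_days,
            f"arms.{name}: horizon shorter than the scheduled pre-ECV waits")
        add(_prob_ok(pval(arm.p_inadequate_first)),
            f"arms.{name}.p_inadequate_first must be in [0,1]")
        add(_prob_ok(pval(arm.p_inadequate_second)),
            f"arms.{name}.p_inadequate_second must be in [0,1]")
        add(pval(arm.drug_cost_per_day) >= 0,
            f"arms.{name}.drug_cost_per_day must be >= 0")

    add(_prob_ok(pval(ps.ecv.p_success)), "ecv.p_success must be in [0,1]")
    add(_prob_ok(pval(ps.ecv.ssr_annual_prob)), "ecv.ssr_annual_prob must be in [0,1]")
    add(_prob_ok(pval(ps.ecv.recurrence_annual_prob)),
        "ecv.recurrence_annual_prob must be in [0,1]")

    for ev in EVENT_NAMES:
        inp: EventInput = getattr(ps.events, ev)
        add(inp.kind in ("rate", "prob"), f"events.{ev}.kind must be 'rate' or 'prob'")
        add(pval(inp.value) >= 0, f"events.{ev} must be >= 0")
        if inp.kind == "prob":
            add(pval(inp.value) <= 1, f"events.{ev} annual probability must be <= 1")
    add(len(ps.events.mortality) > 0, "events.mortality table must be non-empty")
    ages = [a for a, _ in ps.events.mortality]
    add(ages == sorted(ages), "events.mortality ages must be increasing")
    add(all(_prob_ok(q) for _, q in ps.events.mortality),
        "events.mortality entries must be probabilities")

    ut = ps.utilities
    for nm in ("symptomatic_af", "asymptomatic_af", "permanent_af",
               "post_is", "post_mi", "post_ich", "mah", "gih"):
        add(-1.0 <= pval(getattr(ut, nm)) <= 1.0,
            f"utilities.{nm} must be in [-1, 1]")
    add(ut.mih_disutility == 0.0, "utilities.mih_disutility is fixed at 0")
    if ut.mehra is not None:
        w = ut.mehra.weights
        add(abs(sum(w.values()) - 1.0) < 1e-9, "mEHRA weights must sum to 1")
        add(all(v >= 0 for v in w.values()), "mEHRA weights must be >= 0")
        add(all(_prob_ok(u) for u in ut.mehra.utilities.values()),
            "mEHRA class utilities must be in [0,1]")

    cs = ps.costs
    add(abs(cs.inr_mix_service + cs.inr_mix_home - 1.0) < 1e-9,
        "INR monitoring channel mix must sum to 1")
    for nm in ("inr_unit_service", "inr_unit_home", "ecv_tariff",
               "nurse_hourly_wage", "ssr_consult_cost",
               "productivity_per_week", "informal_unit_per_hour"):
        add(pval(getattr(cs, nm)) >= 0, f"costs.{nm} must be >= 0")
    add(set(cs.acute) >= set(EVENT_NAMES), "costs.acute must cover all six events")
    add(set(cs.weekly) >= {"is_", "mi", "ich", "mah", "gih"},
        "costs.weekly must cover IS, MI, ICH, MaH, GIH")
    add(all(pval(v) >= 0 for v in cs.acute.values()), "costs.acute must be >= 0")
    add(all(pval(v) >= 0 for v in cs.weekly.values()), "costs.weekly must be >= 0")
    add(_prob_ok(cs.symptomatic_share_pre), "symptomatic_share_pre must be in [0,1]")
    add(_prob_ok(cs.symptomatic_share_post), "symptomatic_share_post must be in [0,1]")
    add(set(cs.informal_hours) == {"nonintensive", "intensive"},
        "informal_hours must define 'nonintensive' and 'intensive'")

    add(ps.wtp >= 0, "wtp must be >= 0")
    return c


def validation_report(ps: ParameterSet) -> str:
    """Plain-text report, one line per check."""
    lines = []
    for ok, msg in _checks(ps):
        lines.append(("PASS  " if ok else "FAIL  ") + msg)
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# (De)serialization
# ---------------------------------------------------------------------------

def _scalar_to_obj(v: Any, context: str) -> float | UncertainParameter:
    if isinstance(v, dict):
        allowed = {"mean", "se", "family", "bounds"}
        unknown = set(v) - allowed
        if unknown:
            raise ValidationError(f"{context}: unknown keys {sorted(unknown)}")
        if "mean" not in v:
            raise ValidationError(f"{context}: uncertain scalar needs a 'mean'")
        bounds = tuple(v["bounds"]) if v.get("bounds") else None
        return UncertainParameter(mean=float(v["mean"]), se=float(v.get("se", 0.0)),
                                  family=str(v.get("family", "fixed")), bounds=bounds)
    return float(v)


def _scalar_to_plain(v: float | UncertainParameter) -> Any:
    if isinstance(v, UncertainParameter):
        d: dict[str, Any] = {"mean": v.mean, "se": v.se, "family": v.family}
        if v.bounds is not None:
            d["bounds"] = list(v.bounds)
        return d
    return v


def _expect_keys(d: dict, allowed: set[str], required: set[str], context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValidationError(f"{context}: unknown keys {sorted(unknown)}")
    missing = required - set(d)
    if missing:
        raise ValidationError(f"{context}: missing required field(s) {sorted(missing)}")


def parameter_set_from_dict(doc: dict[str, Any]) -> ParameterSet:
    """Build and validate a ParameterSet from a plain (YAML/JSON) mapping."""
    _expect_keys(doc, {"cohort", "schedule", "arms", "ecv", "events", "utilities",
                       "costs", "wtp", "demographics", "age_sd", "metadata"},
                 {"cohort", "arms", "ecv", "events", "utilities", "costs"},
                 "parameter set")

    d = doc["cohort"]
    _expect_keys(d, {"start_age", "male_share", "p_score_lt1", "p_score_lt2",
                     "cohort_size"},
                 {"start_age", "male_share", "p_score_lt1", "p_score_lt2"}, "cohort")
    cohort = CohortProfile(start_age=float(d["start_age"]),
                           male_share=_scalar_to_obj(d["male_share"], "cohort.male_share"),
                           p_score_lt1=float(d["p_score_lt1"]),
                           p_score_lt2=float(d["p_score_lt2"]),
                           cohort_size=int(d.get("cohort_size", 10_000)))

    d = doc.get("schedule", {})
    _expect_keys(d, {"max_attempts", "post_ecv_oac_weeks", "horizon_weeks"}, set(),
                 "schedule")
    schedule = SchedulePolicy(max_attempts=int(d.get("max_attempts", 2)),
                              post_ecv_oac_weeks=int(d.get("post_ecv_oac_weeks", 6)),
                              horizon_weeks=int(d.get("horizon_weeks", 52)))

    arms = {}
    for name, ad in doc["arms"].items():
        if name not in ("riva", "vka"):
            raise ValidationError(f"arms: unknown arm {name!r}")
        _expect_keys(ad, {"pre_ecv_days", "p_inadequate_first", "p_inadequate_second",
                          "drug_cost_per_day", "inr_monitored"},
                     {"pre_ecv_days", "p_inadequate_first", "p_inadequate_second",
                      "drug_cost_per_day"}, f"arms.{name}")
        arms[name] = ArmParameters(
            pre_ecv_days=int(ad["pre_ecv_days"]),
            p_inadequate_first=_scalar_to_obj(ad["p_inadequate_first"],
                                              f"arms.{name}.p_inadequate_first"),
            p_inadequate_second=_scalar_to_obj(ad["p_inadequate_second"],
                                               f"arms.{name}.p_inadequate_second"),
            drug_cost_per_day=_scalar_to_obj(ad["drug_cost_per_day"],
                                             f"arms.{name}.drug_cost_per_day"),
            inr_monitored=bool(ad.get("inr_monitored", name == "vka")))

    d = doc["ecv"]
    _expect_keys(d, {"p_success", "ssr_annual_prob", "recurrence_annual_prob"},
                 {"p_success"}, "ecv")
    ecv = EcvParameters(
        p_success=_scalar_to_obj(d["p_success"], "ecv.p_success"),
        ssr_annual_prob=_scalar_to_obj(d.get("ssr_annual_prob", 0.0),
                                       "ecv.ssr_annual_prob"),
        recurrence_annual_prob=_scalar_to_obj(d.get("recurrence_annual_prob", 0.0),
                                              "ecv.recurrence_annual_prob"))

    d = doc["events"]
    _expect_keys(d, set(EVENT_NAMES) | {"mortality"}, set(EVENT_NAMES) | {"mortality"},
                 "events")
    ev_inputs = {}
    for ev in EVENT_NAMES:
        e = d[ev]
        if isinstance(e, dict) and "value" in e:
            _expect_keys(e, {"value", "kind"}, {"value"}, f"events.{ev}")
            ev_inputs[ev] = EventInput(value=_scalar_to_obj(e["value"], f"events.{ev}"),
                                       kind=str(e.get("kind", "prob")))
        else:
            ev_inputs[ev] = EventInput(value=_scalar_to_obj(e, f"events.{ev}"))
    mortality = [(float(a), float(q)) for a, q in d["mortality"]]
    events = EventRates(**ev_inputs, mortality=mortality)

    d = doc["utilities"]
    _expect_keys(d, {"symptomatic_af", "asymptomatic_af", "permanent_af", "post_is",
                     "post_mi", "post_ich", "mah", "gih", "mih_disutility", "mehra"},
                 {"symptomatic_af", "asymptomatic_af", "permanent_af", "post_is",
                  "post_mi", "post_ich", "mah", "gih"}, "utilities")
    mehra = None
    if d.get("mehra"):
        m = d["mehra"]
        _expect_keys(m, {"weights", "utilities"}, {"weights", "utilities"},
                     "utilities.mehra")
        mehra = MehraDistribution(weights={str(k): float(v) for k, v in m["weights"].items()},
                                  utilities={str(k): float(v) for k, v in m["utilities"].items()})
    utilities = UtilitySet(
        **{nm: _scalar_to_obj(d[nm], f"utilities.{nm}")
           for nm in ("symptomatic_af", "asymptomatic_af", "permanent_af",
                      "post_is", "post_mi", "post_ich", "mah", "gih")},
        mih_disutility=float(d.get("mih_disutility", 0.0)),
        mehra=mehra)

    d = doc["costs"]
    _expect_keys(d, {"inr_unit_service", "inr_unit_home", "inr_mix_service",
                     "inr_mix_home", "inr_pre_ecv_count", "inr_service_per_year",
                     "inr_home_per_year", "ecv_tariff", "lastminute_factor",
                     "nurse_hourly_wage", "early_cancel_minutes", "ssr_consult_cost",
                     "acute", "weekly", "productivity_per_week",
                     "informal_unit_per_hour", "informal_hours",
                     "symptomatic_share_pre", "symptomatic_share_post"},
                 {"inr_unit_service", "inr_unit_home", "ecv_tariff",
                  "nurse_hourly_wage", "ssr_consult_cost", "acute", "weekly",
                  "productivity_per_week", "informal_unit_per_hour"}, "costs")
    costs = CostSet(
        inr_unit_service=_scalar_to_obj(d["inr_unit_service"], "costs.inr_unit_service"),
        inr_unit_home=_scalar_to_obj(d["inr_unit_home"], "costs.inr_unit_home"),
        inr_mix_service=float(d.get("inr_mix_service", 0.569)),
        inr_mix_home=float(d.get("inr_mix_home", 0.431)),
        inr_pre_ecv_count=float(d.get("inr_pre_ecv_count", 5.5)),
        inr_service_per_year=float(d.get("inr_service_per_year", 21.1)),
        inr_home_per_year=float(d.get("inr_home_per_year", 23.5)),
        ecv_tariff=_scalar_to_obj(d["ecv_tariff"], "costs.ecv_tariff"),
        lastminute_factor=float(d.get("lastminute_factor", 0.5)),
        nurse_hourly_wage=_scalar_to_obj(d["nurse_hourly_wage"], "costs.nurse_hourly_wage"),
        early_cancel_minutes=float(d.get("early_cancel_minutes", 30.0)),
        ssr_consult_cost=_scalar_to_obj(d["ssr_consult_cost"], "costs.ssr_consult_cost"),
        acute={k: _scalar_to_obj(v, f"costs.acute.{k}") for k, v in d["acute"].items()},
        weekly={k: _scalar_to_obj(v, f"costs.weekly.{k}") for k, v in d["weekly"].items()},
        productivity_per_week=_scalar_to_obj(d["productivity_per_week"],
                                             "costs.productivity_per_week"),
        informal_unit_per_hour=_scalar_to_obj(d["informal_unit_per_hour"],
                                              "costs.informal_unit_per_hour"),
        informal_hours={str(k): float(v)
                        for k, v in d.get("informal_hours",
                                          {"nonintensive": 8.0, "intensive": 26.0}).items()},
        symptomatic_share_pre=float(d.get("symptomatic_share_pre", 0.70)),
        symptomatic_share_post=float(d.get("symptomatic_share_post", 0.32)))

    demographics = [DemographicsBand(*map(float, row))
                    for row in doc.get("demographics", [])]

    metadata = dict(doc.get("metadata", {}))
    if "wtp" not in doc:
        metadata.setdefault("notices", []).append(
            f"wtp not given; defaulting to {DEFAULT_WTP:.0f} euro/QALY")

    ps = ParameterSet(cohort=cohort, schedule=schedule, arms=arms, ecv=ecv,
                      events=events, utilities=utilities, costs=costs,
                      wtp=float(doc.get("wtp", DEFAULT_WTP)),
                      demographics=demographics,
                      age_sd=float(doc.get("age_sd", 10.8)),
                      metadata=metadata)
    ps.validate()
    return ps


def parameter_set_to_dict(ps: ParameterSet) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "cohort": {"start_age": ps.cohort.start_age,
                   "male_share": _scalar_to_plain(ps.cohort.male_share),
                   "p_score_lt1": ps.cohort.p_score_lt1,
                   "p_score_lt2": ps.cohort.p_score_lt2,
                   "cohort_size": ps.cohort.cohort_size},
        "schedule": dataclasses.asdict(ps.schedule),
        "arms": {name: {"pre_ecv_days": a.pre_ecv_days,
                        "p_inadequate_first": _scalar_to_plain(a.p_inadequate_first),
                        "p_inadequate_second": _scalar_to_plain(a.p_inadequate_second),
                        "drug_cost_per_day": _scalar_to_plain(a.drug_cost_per_day),
                        "inr_monitored": a.inr_monitored}
                 for name, a in sorted(ps.arms.items())},
        "ecv": {"p_success": _scalar_to_plain(ps.ecv.p_success),
                "ssr_annual_prob": _scalar_to_plain(ps.ecv.ssr_annual_prob),
                "recurrence_annual_prob": _scalar_to_plain(ps.ecv.recurrence_annual_prob)},
        "events": {**{ev: {"value": _scalar_to_plain(getattr(ps.events, ev).value),
                           "kind": getattr(ps.events, ev).kind}
                      for ev in EVENT_NAMES},
                   "mortality": [[a, q] for a, q in ps.events.mortality]},
        "utilities": {**{nm: _scalar_to_plain(getattr(ps.utilities, nm))
                         for nm in ("symptomatic_af", "asymptomatic_af", "permanent_af",
                                    "post_is", "post_mi", "post_ich", "mah", "gih")},
                      "mih_disutility": ps.utilities.mih_disutility},
        "costs": {"inr_unit_service": _scalar_to_plain(ps.costs.inr_unit_service),
                  "inr_unit_home": _scalar_to_plain(ps.costs.inr_unit_home),
                  "inr_mix_service": ps.costs.inr_mix_service,
                  "inr_mix_home": ps.costs.inr_mix_home,
                  "inr_pre_ecv_count": ps.costs.inr_pre_ecv_count,
                  "inr_service_per_year": ps.costs.inr_service_per_year,
                  "inr_home_per_year": ps.costs.inr_home_per_year,
                  "ecv_tariff": _scalar_to_plain(ps.costs.ecv_tariff),
                  "lastminute_factor": ps.costs.lastminute_factor,
                  "nurse_hourly_wage": _scalar_to_plain(ps.costs.nurse_hourly_wage),
                  "early_cancel_minutes": ps.costs.early_cancel_minutes,
                  "ssr_consult_cost": _scalar_to_plain(ps.costs.ssr_consult_cost),
                  "acute": {k: _scalar_to_plain(v) for k, v in sorted(ps.costs.acute.items())},
                  "weekly": {k: _scalar_to_plain(v) for k, v in sorted(ps.costs.weekly.items())},
                  "productivity_per_week": _scalar_to_plain(ps.costs.productivity_per_week),
                  "informal_unit_per_hour": _scalar_to_plain(ps.costs.informal_unit_per_hour),
                  "informal_hours": dict(ps.costs.informal_hours),
                  "symptomatic_share_pre": ps.costs.symptomatic_share_pre,
                  "symptomatic_share_post": ps.costs.symptomatic_share_post},
        "wtp": ps.wtp,
        "age_sd": ps.age_sd,
        "demographics": [[b.age_lo, b.age_hi, b.participation, b.hours_per_week,
                          b.gross_monthly_salary] for b in ps.demographics],
        "metadata": dict(ps.metadata),
    }
    if ps.utilities.mehra is not None:
        doc["utilities"]["mehra"] = {"weights": dict(ps.utilities.mehra.weights),
                                     "utilities": dict(ps.utilities.mehra.utilities)}
    return doc


def base_case_parameters() -> ParameterSet:
    """The bundled base-case configuration (main-text quantities at their
    printed values, remaining inputs synthetic plausibility draws)."""
    from importlib.resources import files
    path = files("cardiovert").joinpath("data/base_case.yaml")
    return parameter_set_from_dict(yaml.safe_load(path.read_text()))


def load_parameter_set(config_path: str | Path) -> ParameterSet:
    """Load, validate and return a ParameterSet from a YAML (or JSON) file."""
    path = Path(config_path)
    with path.open() as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: config must be a mapping at the top level")
    return parameter_set_from_dict(doc)


def save_parameter_set(ps: ParameterSet, config_path: str | Path) -> None:
    with Path(config_path).open("w") as fh:
        yaml.safe_dump(parameter_set_to_dict(ps), fh, sort_keys=False)
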