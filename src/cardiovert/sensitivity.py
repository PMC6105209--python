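"""Univariate (one-way) scenario analyses and the tornado summary.

The standard suite varies age, sex and VKA anticoagulation inadequacy by
+/-20% of the mean, ECV-related and non-health-care costs by x0.5/x2, the
rivaroxaban pre-ECV anticoagulation period over {12, 30} days, the ECV
success rate by +/-20% (clipped to 1), and sets rivaroxaban inadequacy equal
to the VKA level (the nonadherence scenario).  The age scenario shifts both
the mortality lookup and the productivity-loss weighting.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import pandas as pd

from .params import ParameterSet, UncertainParameter, pval
from .psa import deterministic_ce
from .synth import productivity_loss_unit_cost

__all__ = ["Scenario", "apply_overrides", "run_scenario",
           "paper_scenario_suite", "tornado"]


@dataclass
class Scenario:
    name: str
    side: str                       # 'low', 'high', or 'base'
    overrides: dict[str, float] = field(default_factory=dict)
    perspective: str = "societal"


def _set_path(ps: ParameterSet, path: str, value: float) -> None:
    parts = path.split(".")
    obj = ps
    for p in parts[:-1]:
        if isinstance(obj, dict):
            if p not in obj:
                raise KeyError(f"override path {path!r}: no key {p!r}")
            obj = obj[p]
        else:
            if not hasattr(obj, p):
                raise KeyError(f"override path {path!r}: no field {p!r}")
            obj = getattr(obj, p)
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"override path {path!r}: no key {leaf!r}")
        cur = obj[leaf]
        obj[leaf] = _retype(cur, value)
    else:
        if not hasattr(obj, leaf):
            raise KeyError(f"override path {path!r}: no field {leaf!r}")
        cur = getattr(obj, leaf)
        setattr(obj, leaf, _retype(cur, value))


def _retype(current, value: float):
    """Preserve the container type of the overridden field."""
    if isinstance(current, UncertainParameter):
        # a scenario pins the point value; uncertainty metadata is irrelevant
        return UncertainParameter(mean=float(value), family="fixed")
    if isinstance(current, int) and not isinstance(current, bool):
        return int(round(value))
    return float(value)


def apply_overrides(base: ParameterSet, overrides: dict[str, float]
                    ) -> ParameterSet:
    """Return a deep copy of the parameter set with overrides applied;
    the base object is never modified."""
    ps = copy.deepcopy(base)
    for path, value in overrides.items():
        _set_path(ps, path, value)
    ps.validate()
    return ps


def run_scenario(base: ParameterSet, scenario: Scenario):
    """Deterministic pipeline run with the scenario's overrides applied to
    both arms; returns the CEResult."""
    ps = apply_overrides(base, scenario.overrides)
    ce, _ = deterministic_ce(ps, scenario.perspective)
    return ce


def paper_scenario_suite(base: ParameterSet,
                         perspective: str = "societal") -> list[Scenario]:
    """The standard univariate suite around the base case."""
    sc: list[Scenario] = []

    def add(name: str, side: str, overrides: dict[str, float]) -> None:
        sc.append(Scenario(name=name, side=side, overrides=overrides,
                           perspective=perspective))

    age0 = base.cohort.start_age
    for side, f in (("low", 0.8), ("high", 1.2)):
        age = age0 * f
        ov = {"cohort.start_age": age}
        if base.demographics:
            ov["costs.productivity_per_week"] = productivity_loss_unit_cost(
                base.demographics, mean_age=age, sd_age=base.age_sd)
        add("age", side, ov)

    male0 = pval(base.cohort.male_share)
    for side, f in (("low", 0.8), ("high", 1.2)):
        add("male_share", side,
            {"cohort.male_share": min(max(male0 * f, 0.0), 1.0)})

    for side, f in (("low", 0.8), ("high", 1.2)):
        add("vka_inadequate", side, {
            "arms.vka.p_inadequate_first":
                min(pval(base.arms["vka"].p_inadequate_first) * f, 1.0),
            "arms.vka.p_inadequate_second":
                min(pval(base.arms["vka"].p_inadequate_second) * f, 1.0)})

    for side, f in (("low", 0.8), ("high", 1.2)):
        add("ecv_success", side,
            {"ecv.p_success": min(pval(base.ecv.p_success) * f, 1.0)})

    for side, days in (("low", 12), ("high", 30)):
        add("riva_pre_ecv_days", side, {"arms.riva.pre_ecv_days": days})

    add("riva_nonadherence", "high",
        {"arms.riva.p_inadequate_first":
             pval(base.arms["vka"].p_inadequate_first)})

    for side, f in (("low", 0.5), ("high", 2.0)):
        add("ecv_costs", side, {
            "costs.ecv_tariff": pval(base.costs.ecv_tariff) * f,
            "costs.nurse_hourly_wage": pval(base.costs.nurse_hourly_wage) * f,
            "costs.ssr_consult_cost": pval(base.costs.ssr_consult_cost) * f})

    for side, f in (("low", 0.5), ("high", 2.0)):
        add("nonhealth_costs", side, {
            "costs.productivity_per_week":
                pval(base.costs.productivity_per_week) * f,
            "costs.informal_unit_per_hour":
                pval(base.costs.informal_unit_per_hour) * f})

    return sc


def tornado(base: ParameterSet, suite: list[Scenario],
            perspective: str = "societal") -> pd.DataFrame:
    """One row per scenario: incremental cost/QALYs at the lower and upper
    settings, sorted by the incremental-cost span (widest bar first).
    One-sided scenarios use the base case as their other end."""
    if not suite:
        raise ValueError("scenario suite is empty")
    base_ce, _ = deterministic_ce(base, perspective)
    results: dict[str, dict[str, tuple[float, float]]] = {}
    for s in suite:
        s = Scenario(s.name, s.side, s.overrides, perspective)
        ce = run_scenario(base, s)
        results.setdefault(s.name, {})[s.side] = (ce.delta_cost, ce.delta_qalys)
    rows = []
    for name, sides in results.items():
        lo = sides.get("low", (base_ce.delta_cost, base_ce.delta_qalys))
        hi = sides.get("high", (base_ce.delta_cost, base_ce.delta_qalys))
        rows.append({"scenario": name,
                     "delta_cost_low": lo[0], "delta_cost_high": hi[0],
                     "delta_qalys_low": lo[1], "delta_qalys_high": hi[1],
                     "cost_span": abs(hi[0] - lo[0]),
                     "base_delta_cost": base_ce.delta_cost,
                     "base_delta_qalys": base_ce.delta_qalys})
    df = pd.DataFrame(rows).sort_values("cost_span", ascending=False,
                                        ignore_index=True)
    return df
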