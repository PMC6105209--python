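"""Shared fixtures: synthetic parameter sets and degenerate variants."""

from __future__ import annotations

import copy
import dataclasses

import pytest

from cardiovert import base_case_parameters, generate_parameter_set
from cardiovert.params import EventInput, ParameterSet, UncertainParameter


@pytest.fixture(scope="session")
def base_ps() -> ParameterSet:
    """A base-case-like synthetic parameter set (frozen seed)."""
    return generate_parameter_set(1, "base_like")


@pytest.fixture(scope="session")
def bundled_ps() -> ParameterSet:
    """The configuration shipped with the package."""
    return base_case_parameters()


def fix_all_parameters(ps: ParameterSet) -> ParameterSet:
    """Deep copy with every uncertain parameter collapsed to its mean."""
    out = copy.deepcopy(ps)

    def walk(obj):
        if isinstance(obj, UncertainParameter):
            return UncertainParameter(mean=obj.mean, family="fixed")
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            for f in dataclasses.fields(obj):
                setattr(obj, f.name, walk(getattr(obj, f.name)))
            return obj
        if isinstance(obj, dict):
            return {k: walk(v) for k, v in obj.items()}
        if isinstance(obj, list):
            return [walk(v) for v in obj]
        return obj

    return walk(out)


def forced_path_parameters(ps: ParameterSet) -> ParameterSet:
    """Deterministic degenerate inputs: no events, no deaths, no spontaneous
    conversion or recurrence, every first ECV adequate and successful."""
    out = fix_all_parameters(ps)
    for ev in ("is_", "mi", "ich", "mah", "gih", "mih"):
        setattr(out.events, ev, EventInput(value=0.0, kind="prob"))
    out.events.mortality = [(0.0, 0.0)]
    out.ecv.p_success = 1.0
    out.ecv.ssr_annual_prob = 0.0
    out.ecv.recurrence_annual_prob = 0.0
    for arm in out.arms.values():
        arm.p_inadequate_first = 0.0
        arm.p_inadequate_second = 0.0
    out.validate()
    return out


def equalized_arms(ps: ParameterSet) -> ParameterSet:
    """Deep copy with the VKA arm made fully identical to the rivaroxaban
    arm (including monitoring), for the equal-arm null."""
    out = copy.deepcopy(ps)
    out.arms["vka"] = copy.deepcopy(out.arms["riva"])
    out.validate()
    return out


@pytest.fixture()
def forced_ps(base_ps) -> ParameterSet:
    return forced_path_parameters(base_ps)
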