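"""Probabilistic sensitivity analysis.

Parameters carrying uncertainty (beta for probabilities and utilities, gamma
for costs; drug and indirect costs fixed) are re-drawn each iteration from
their method-of-moments distributions, the full two-arm pipeline is re-run,
and the incremental cost/QALY pairs summarize the cost-effectiveness plane,
the acceptability curve (CEAC), and the probability of cost saving.

Each iteration draws from its own SeedSequence-spawned substream, so results
are reproducible and independent of execution order.  A parameter shared by
both arms (event rates, utilities, the ECV success rate) is stored once in
the ParameterSet and therefore receives the identical draw in both arms.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import build_model, run_cohort
from .outcomes import CEResult, OutcomeSummary, compare_arms, summarize
from .params import (ParameterSet, UncertainParameter, beta_from_mean_se,
                     gamma_from_mean_se)

__all__ = ["PSAResult", "sample_parameters", "run_psa", "run_psa_both",
           "ceac", "prob_cost_saving", "ce_plane_frame", "ceac_frame",
           "deterministic_ce"]


def deterministic_ce(params: ParameterSet, perspective: str
                     ) -> tuple[CEResult, dict[str, OutcomeSummary]]:
    """Run both arms at the parameter means and compare them."""
    out = {arm: summarize(run_cohort(build_model(params, arm)), params, perspective)
           for arm in ("riva", "vka")}
    return compare_arms(out["riva"], out["vka"], params.wtp), out


def _draw_scalar(u: UncertainParameter, rng: np.random.Generator,
                 truncate: bool) -> float | UncertainParameter:
    if u.family == "fixed" or u.se == 0.0:
        return u
    if u.family == "beta":
        alpha, beta = beta_from_mean_se(u.mean, u.se)
        x = float(rng.beta(alpha, beta))
    else:
        shape, scale = gamma_from_mean_se(u.mean, u.se)
        x = float(rng.gamma(shape, scale))
    if truncate:
        lo, hi = u.mean - 1.96 * u.se, u.mean + 1.96 * u.se
        x = min(max(x, lo), hi)
    if u.bounds is not None:
        x = min(max(x, u.bounds[0]), u.bounds[1])
    return x


def _sample_tree(obj, rng: np.random.Generator, truncate: bool):
    if isinstance(obj, UncertainParameter):
        return _draw_scalar(obj, rng, truncate)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        for f in dataclasses.fields(obj):
            setattr(obj, f.name, _sample_tree(getattr(obj, f.name), rng, truncate))
        return obj
    if isinstance(obj, dict):
        for k in sorted(obj, key=str):
            obj[k] = _sample_tree(obj[k], rng, truncate)
        return obj
    if isinstance(obj, list):
        return [_sample_tree(v, rng, truncate) for v in obj]
    return obj


def sample_parameters(params: ParameterSet, rng: np.random.Generator,
                      truncate: bool = False) -> ParameterSet:
    """One Monte-Carlo draw of every uncertain parameter.

    Fixed-family and zero-SE parameters pass through untouched; with
    ``truncate`` draws are clipped to the mean +/- 1.96 SE interval (the
    95%-interval reading of parameter variation; off by default since the
    beta/gamma families already encode the uncertainty).
    """
    drawn = copy.deepcopy(params)
    drawn.metadata = dict(params.metadata)
    _sample_tree(drawn, rng, truncate)
    return drawn


@dataclass
class PSAResult:
    n_iterations: int
    seed: int
    perspective: str
    delta_cost: np.ndarray     # (n,)
    delta_qalys: np.ndarray    # (n,)


def _psa_iterations(params: ParameterSet, n_iterations: int, seed: int,
                    truncate: bool) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-iteration (societal ΔC, payer ΔC, ΔQ)."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    dc_soc = np.empty(n_iterations)
    dc_pay = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    for i, ss in enumerate(streams):
        try:
            drawn = sample_parameters(params, np.random.default_rng(ss), truncate)
            res = {}
            for arm in ("riva", "vka"):
                trace = run_cohort(build_model(drawn, arm))
                res[arm] = summarize(trace, drawn, "societal")
            ce = compare_arms(res["riva"], res["vka"], drawn.wtp)
            nonhealth = {arm: sum(res[arm].costs[c]
                                  for c in ("productivity_loss", "informal_care"))
                         for arm in res}
            dc_soc[i] = ce.delta_cost
            dc_pay[i] = ce.delta_cost - (nonhealth["riva"] - nonhealth["vka"])
            dq[i] = ce.delta_qalys
        except Exception as exc:  # noqa: BLE001 - annotate the failing iteration
            raise RuntimeError(f"PSA iteration {i} failed: {exc}") from exc
    return dc_soc, dc_pay, dq


def run_psa(params: ParameterSet, n_iterations: int, seed: int,
            perspective: str = "societal", truncate: bool = False) -> PSAResult:
    """Full probabilistic sensitivity analysis; deterministic given seed."""
    dc_soc, dc_pay, dq = _psa_iterations(params, n_iterations, seed, truncate)
    dc = dc_soc if perspective == "societal" else dc_pay
    if perspective not in ("societal", "payer"):
        raise ValueError(f"unknown perspective {perspective!r}")
    return PSAResult(n_iterations=n_iterations, seed=seed, perspective=perspective,
                     delta_cost=dc, delta_qalys=dq)


def run_psa_both(params: ParameterSet, n_iterations: int, seed: int,
                 truncate: bool = False) -> dict[str, PSAResult]:
    """Societal and payer PSA from the same parameter draws (one model pass)."""
    dc_soc, dc_pay, dq = _psa_iterations(params, n_iterations, seed, truncate)
    return {"societal": PSAResult(n_iterations, seed, "societal", dc_soc, dq),
            "payer": PSAResult(n_iterations, seed, "payer", dc_pay, dq)}


def ceac(psa: PSAResult, wtp_grid) -> np.ndarray:
    """Cost-effectiveness acceptability curve: for each willingness-to-pay
    level, the fraction of iterations with positive net monetary benefit."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    nmb = grid[:, None] * psa.delta_qalys[None, :] - psa.delta_cost[None, :]
    return (nmb > 0).mean(axis=1)


def prob_cost_saving(psa: PSAResult) -> float:
    """Fraction of iterations in which rivaroxaban saves money outright."""
    if psa.n_iterations == 0:
        raise ValueError("empty PSA result")
    return float((psa.delta_cost < 0).mean())


def ce_plane_frame(psa: PSAResult) -> pd.DataFrame:
    return pd.DataFrame({"iteration": np.arange(psa.n_iterations),
                         "delta_cost": psa.delta_cost,
                         "delta_qalys": psa.delta_qalys})


def ceac_frame(psa: PSAResult, wtp_grid) -> pd.DataFrame:
    grid = np.asarray(wtp_grid, dtype=float)
    return pd.DataFrame({"wtp": grid, "prob_cost_effective": ceac(psa, grid)})
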