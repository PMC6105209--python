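# cardiovert

Cost-effectiveness of **rivaroxaban versus vitamin K antagonists (VKA)**
around elective electrical cardioversion (ECV) of atrial fibrillation, over a
1-year horizon, from the societal and health-care payer perspectives.

Rivaroxaban reaches stable anticoagulation faster than dose-adjusted VKA
(a 22- vs 30-day wait before the procedure) and essentially never arrives
inadequately anticoagulated on the day of the procedure (0.24% vs 44.19% of
first attempts), so fewer cardioversions are cancelled last-minute, less time
is spent in symptomatic AF, and no INR monitoring is needed. The package
quantifies what that is worth: a two-phase Markov cohort model (daily cycles
while waiting, weekly cycles to one year) with explicit scheduling and
cancellation logic, clinical events (stroke, myocardial infarction,
intracranial/major/gastrointestinal/minor hemorrhage), QALY and
categorized-cost accounting, probabilistic and univariate sensitivity
analysis, and an individual-level micro-simulation used as a validation
oracle. See [docs/methods.md](docs/methods.md) for the full model
description.

## Worked example

```python
from cardiovert import (base_case_parameters, build_model, run_cohort,
                        summarize, compare_arms)

params = base_case_parameters()          # bundled, validated configuration
for perspective in ("societal", "payer"):
    out = {arm: summarize(run_cohort(build_model(params, arm)), params, perspective)
           for arm in ("riva", "vka")}
    ce = compare_arms(out["riva"], out["vka"], params.wtp)
    print(perspective, f"dC={ce.delta_cost:+.0f}", f"dQ={ce.delta_qalys:+.4f}",
          ce.dominance)
```

Running `python examples/01_deterministic_base_case.py` prints:

```
perspective  arm  cost_per_patient  qalys  delta_cost  delta_qalys        icer    dominance
   societal riva          6,960.47   0.76   -1,720.79         0.02 -108,489.96     dominant
   societal  vka          8,681.26   0.74         NaN          NaN         NaN
      payer riva          2,657.18   0.76      278.76         0.02   17,574.67 trade-off NE
      payer  vka          2,378.42   0.74         NaN          NaN         NaN

societal: dC = -1,721 euro, dQ = +0.0159 QALYs, NMB = 2,038 euro (dominant)
   payer: dC = +279 euro, dQ = +0.0159 QALYs, NMB = 38 euro (trade-off NE)
```

Under the bundled inputs rivaroxaban is dominant from the societal
perspective — it saves money (mostly productivity and informal-care costs of
the longer symptomatic wait on VKA, plus INR monitoring and cancelled
procedures) while gaining QALYs — and is a modest trade-off from the payer
perspective, where the indirect savings do not count and the higher drug
price remains.

The other examples walk through each capability:

| script | shows |
|---|---|
| `examples/01_deterministic_base_case.py` | headline table and cost breakdown |
| `examples/02_probabilistic_sensitivity.py` | PSA, CEAC, P(cost saving) |
| `examples/03_scenario_tornado.py` | univariate scenarios, tornado ordering |
| `examples/04_microsim_crossvalidation.py` | engine vs 20k-patient micro-simulation |
| `examples/05_generate_configs.py` | synthetic config generation + provenance |

A thin CLI wraps the same pipeline for config-driven use:

```bash
cardiovert generate --seed 7 --out config.yaml
cardiovert validate config.yaml
cardiovert run config.yaml --out results/
cardiovert psa config.yaml -n 1000 --seed 11 --out results/
cardiovert tornado config.yaml --out results/
```

## Inputs

`base_case_parameters()` returns the bundled configuration; any configuration
is a plain YAML file (`load_parameter_set` / `save_parameter_set`) validated
against the full invariant set on load. Headline quantities are fixed at
their published values; unpublished inputs (event probabilities, utilities,
unit costs, life table, labour-market table) are synthetic draws from
documented plausibility ranges — `cardiovert.synth.provenance()` labels every
field. Absolute magnitudes therefore depend on the synthetic inputs; the
directional conclusions are robust across generator seeds (see the methods
note for limits).

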