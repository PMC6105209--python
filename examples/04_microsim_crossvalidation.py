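"""Cross-validate the cohort engine against the individual-level
micro-simulation: every reported quantity (QALYs, each cost category, the
total) should lie within 3 Monte-Carlo standard errors of the simulated
mean.

Run with:  python examples/04_microsim_crossvalidation.py
"""

from cardiovert import (base_case_parameters, build_model, crossvalidate,
                        run_cohort, simulate_individuals, summarize)

N = 20_000
SEED = 2_024

params = base_case_parameters()
for arm in ("riva", "vka"):
    cohort = summarize(run_cohort(build_model(params, arm)), params, "societal")
    micro = simulate_individuals(params, arm, N, seed=SEED)
    df = crossvalidate(cohort, micro)
    print(f"--- {arm} ({N} simulated patients) ---")
    print(df.to_string(index=False, float_format=lambda x: f"{x:,.4f}"))
    print("all quantities agree" if df["pass"].all()
          else "DISAGREEMENT detected")
    print()
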