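"""Deterministic base case: run both arms at the parameter means and print
the headline cost-effectiveness table in both perspectives.

Run with:  python examples/01_deterministic_base_case.py
"""

from cardiovert import (base_case_parameters, build_model, compare_arms,
                        results_table, run_cohort, summarize)

params = base_case_parameters()

summaries = {}
for perspective in ("societal", "payer"):
    summaries[perspective] = {
        arm: summarize(run_cohort(build_model(params, arm)), params, perspective)
        for arm in ("riva", "vka")}

table = results_table(summaries, params.wtp)
print(table.to_string(index=False, float_format=lambda x: f"{x:,.2f}"))

print()
for perspective, by_arm in summaries.items():
    ce = compare_arms(by_arm["riva"], by_arm["vka"], params.wtp)
    print(f"{perspective:>8}: dC = {ce.delta_cost:+,.0f} euro, "
          f"dQ = {ce.delta_qalys:+.4f} QALYs, NMB = {ce.nmb:,.0f} euro "
          f"({ce.dominance})")

print("\nCost breakdown, societal perspective (euro per patient):")
for arm in ("riva", "vka"):
    s = summaries["societal"][arm]
    parts = ", ".join(f"{k} {v:,.0f}" for k, v in s.costs.items())
    print(f"  {arm}: total {s.total_cost:,.0f}  [{parts}]")
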