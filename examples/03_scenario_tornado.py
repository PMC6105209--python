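"""Univariate scenario analyses: the standard suite (age, sex, VKA
anticoagulation adequacy, ECV success, rivaroxaban waiting time and
adherence, procedure and non-health-care costs) and the tornado summary
sorted by incremental-cost span.

Run with:  python examples/03_scenario_tornado.py
"""

from cardiovert import base_case_parameters, paper_scenario_suite, tornado

params = base_case_parameters()
suite = paper_scenario_suite(params, perspective="societal")
df = tornado(params, suite, perspective="societal")

print(f"base case: dC = {df['base_delta_cost'].iloc[0]:+,.0f} euro, "
      f"dQ = {df['base_delta_qalys'].iloc[0]:+.4f} QALYs\n")
cols = ["scenario", "delta_cost_low", "delta_cost_high", "cost_span",
        "delta_qalys_low", "delta_qalys_high"]
print(df[cols].to_string(index=False, float_format=lambda x: f"{x:,.2f}"))
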