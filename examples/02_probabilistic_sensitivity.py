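"""Probabilistic sensitivity analysis: re-draw every uncertain parameter,
re-run the model, and summarize the cost-effectiveness plane and
acceptability curve.  Uses 1,000 iterations for a quick demonstration;
increase N for production-quality curves.

Run with:  python examples/02_probabilistic_sensitivity.py
"""

import numpy as np

from cardiovert import base_case_parameters, ceac, prob_cost_saving, run_psa_both

N = 1_000
SEED = 20_240_101

params = base_case_parameters()
psa = run_psa_both(params, N, seed=SEED)

grid = np.linspace(0, 80_000, 9)
for perspective, res in psa.items():
    print(f"--- {perspective} perspective ({N} iterations) ---")
    print(f"  mean dC = {res.delta_cost.mean():+,.0f} euro "
          f"(2.5-97.5%: {np.percentile(res.delta_cost, 2.5):+,.0f} to "
          f"{np.percentile(res.delta_cost, 97.5):+,.0f})")
    print(f"  mean dQ = {res.delta_qalys.mean():+.4f} QALYs")
    print(f"  P(cost saving)                = {prob_cost_saving(res):.3f}")
    curve = ceac(res, grid)
    print(f"  P(cost-effective at 20k/QALY) = {curve[2]:.3f}")
    print("  CEAC:", "  ".join(f"{int(w/1000)}k:{p:.2f}"
                               for w, p in zip(grid, curve)))
    print()
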