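"""The full workflow: detect infeasibility, balance, then FBA/FVA.

After correcting the scenario, flux variability analysis identifies the
rates that are uniquely determined (identical minimum and maximum flux) --
including ones that kernel analysis alone cannot see, because they follow
from irreversibility rather than from the balances.
"""

import fluxbalancer as fb

model = fb.example_network()  # 10 reactions, 6 metabolites, full rank
scenario = fb.FluxScenario(fixed={"R1": 1.0, "R2": 2.0, "R3": 1.5, "R4": 2.0})

print("FBA on the raw scenario:",
      fb.fba(model, scenario, objective={"R4": 1.0}).status)

diag = fb.diagnose(model, scenario)
print(f"degR = {diag.degR}; redundant rates: {diag.redundant_rate_ids}")

res = fb.qp_balance(model, scenario, "W3")
corrected = fb.apply_corrections(scenario, res)
print("corrected exchange rates:",
      {r: round(v, 4) for r, v in res.corrected_values.items()})

ranges = fb.fva(model, corrected, feasibility_tol=1e-6)
print("determined rates:", sorted(fb.determined_rates(ranges)))
for rid, (lo, hi) in ranges.ranges.items():
    print(f"  {rid}: [{lo:.4g}, {hi:.4g}]")
print()
print("The four measured exchange rates violated the overall balance")
print("r1 + r2 = r3 + r4 by 0.5; the QP spread that correction equally.")
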