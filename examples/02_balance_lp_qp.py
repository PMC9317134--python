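"""Correct an inconsistent scenario by LP and QP balancing.

The coupled pair fixed at (2, 4) is reconciled with magnitude weights
w_i = 1/|f_i| = (1/2, 1/4): the LP (sum of weighted absolute changes) moves
only the cheaper-to-change larger rate, giving (2, 2); the QP (sum of
weighted squared changes) spreads the correction, giving 8/3 = 2.67.
"""

import fluxbalancer as fb

model = fb.coupled_pair()
scenario = fb.FluxScenario(fixed={"R4": 2.0, "R10": 4.0})

for engine, label in [(fb.lp_balance, "LP"), (fb.qp_balance, "QP")]:
    res = engine(model, scenario, "W2")
    print(f"{label} (w = 1/|f|): corrected values "
          f"{ {r: round(v, 4) for r, v in res.corrected_values.items()} }, "
          f"objective {res.objective_value:.4g}")

res = fb.lp_balance(model, scenario, "W3", check_uniqueness=True)
print(f"LP (equal weights): objective {res.objective_value:.4g}, "
      f"unique = {res.unique}")
print()
print("With equal weights the LP optimum is a whole face: any common value")
print("in [2, 4] costs 2 in total absolute change, so the solution returned")
print("depends on the solver -- the uniqueness check reports that.")
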