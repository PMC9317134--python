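"""Correct constraints other than the fixed rates.

When the fixed rates are trusted, the inconsistency can instead be absorbed
by slacks on other constraint classes.  With steady-state slacks and equal
weights, the QP slacks reproduce the steady-state residual of the classical
pseudoinverse solution.
"""

import numpy as np

import fluxbalancer as fb

chain = fb.chain3()  # R1 -> A -> R2 -> B -> R3
scenario = fb.FluxScenario(fixed={"R1": 5.0, "R3": 7.0})  # 5 in, 7 out

res = fb.generalized_balance(chain, scenario, targets={"steady_state"}, engine="qp")
print("steady-state slacks:", {m: round(v, 6) for m, v in
                               res.constraint_slacks["steady_state"].items()})

part = fb.partition(chain, scenario)
r = np.zeros(3)
r[part.U] = fb.pseudoinverse_solution(part)  # r2 = 6, the least-squares value
r[part.F] = part.rF
print("pseudoinverse residual N r:", chain.N @ r)
print()
print("Both give (-1, -1): metabolites A and B each drain at rate 1, the")
print("minimal steady-state violation compatible with keeping R1=5, R3=7.")
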