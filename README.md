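# fluxbalancer

Diagnose and resolve infeasible flux-balance scenarios in metabolic network
models.

## The problem

Constraint-based models describe a metabolic network with *m* metabolites and
*n* reactions by its stoichiometric matrix **N**. A steady-state flux vector
**r** satisfies

```
N r = 0,        lb_i <= r_i <= ub_i,        A r <= b,
```

and flux balance analysis (FBA) maximizes a linear objective `c'r` over this
polyhedron. In practice, one often *fixes* a subset `F` of rates to measured
or assumed values, `r_i = f_i` — growth rate, substrate uptake, product
excretion. Because measurements carry noise and stoichiometric balances link
them, these values are frequently mutually inconsistent and the LP becomes
infeasible. fluxbalancer classifies such scenarios, identifies which fixed
rates are responsible, and computes minimal corrections that restore
feasibility, after which FBA/FVA can proceed.

## What it computes

**Classification** (classical MFA on the split system `N_U r_U = -N_F r_F`):

* determinacy — `rank(N_U) = x` means every unknown rate is uniquely
  calculable; the uniquely determined unknowns are the zero rows of a
  nullspace basis of `N_U`;
* redundancy — `degR = rank(N) - rank(N_U)` new row dependencies created by
  fixing rates (conservation relations never count);
* consistency — `R r_F = 0`, with the redundancy matrix
  `R = N_F - N_U N_U^+ N_F`; non-zero columns of `R` mark the fixed rates
  involved in the redundancy.

**Correction**, three engines sharing weighting schemes W1 (`w_i = 1/σ_i²`),
W2 (`w_i = 1/|f_i|`) and W3 (`w_i = 1`):

* analytical WLS: `δ = W R_r' (R_r W R_r')⁻¹ R_r r_F` with `W = diag(1/w_i)`
  and `R_r` a maximal independent row set of `R` (steady state only);
* QP: `min Σ w_i δ_i²` subject to the *full* constraint set (bounds and
  general constraints included), unique corrections;
* LP: `min Σ w_i (δ_i⁺ + δ_i⁻)` with paired non-negative slacks — the
  weighted sum of absolute changes; unique objective, possibly non-unique
  corrections (an optional check explores the optimal face).

Generalized balancing puts slacks on other constraint classes (steady-state
rows, bounds, general inequalities) instead of or in addition to the fixed
rates. FBA and FVA on the corrected system finish the workflow; FVA flags
the rates with identical minimum and maximum flux as uniquely determined.

## Worked example

The minimal strictly coupled pair `R4 -> D -> R10` (one balance forces
`r_R4 = r_R10`) with measured rates `R4 = 2`, `R10 = 4`:

```python
import fluxbalancer as fb

model = fb.coupled_pair()
scenario = fb.FluxScenario(fixed={"R4": 2.0, "R10": 4.0})
print(fb.diagnose(model, scenario).summary())
res = fb.qp_balance(model, scenario, "W2")   # weights 1/|f| = (1/2, 1/4)
print(res.corrected_values)
```

prints

```
determinacy:   determined (dof = 0)
redundancy:    redundant (degR = 1)
consistency:   inconsistent (max |R rF| = 2)
conservation relations: 0
redundant rates: R4, R10
{'R4': 2.666666666666667, 'R10': 2.6666666666666665}
```

One balance links the two rates (`degR = 1`), the measured values violate it
by 2, and the magnitude-weighted QP reconciles both rates at 8/3 ≈ 2.67
(the cheaper-to-change larger rate moves more). The LP engine with the same
weights instead gives the corner solution (2, 2); with equal weights its
optimum is a whole face — any common value in [2, 4] — which
`check_uniqueness=True` reports. See `examples/` for narrative scripts
covering classification, balancing, generalized slacks, the FBA/FVA
workflow and noise recovery on synthetic scenarios, and
`fluxbalancer --help` for the command-line interface
(`classify | balance | fba | fva | demo`).

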