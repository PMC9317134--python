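# Methods

## Model and scenario

A metabolic network is the stoichiometric matrix `N` (m metabolites x n
reactions) with per-reaction flux bounds `lb <= r <= ub` (flux units, e.g.
mmol·gDW⁻¹·h⁻¹; ±inf allowed, encoded ±1e30 in files), optional general
linear inequalities `A r <= b` (e.g. enzyme-capacity budgets) and an
optional linear objective `c`. A flux scenario fixes a subset `F` of rates,
`r_i = f_i`, optionally with measurement variances `σ_i²`. Fixed rates are
kept out of the bounds: a model reaction clamped by `lb = ub` is imported
into the scenario's fixed set on load, and a conflicting explicit value is
an error rather than a silent override.

## Classification

Splitting `N r = 0` by fixed/unknown columns gives `N_U r_U = -N_F r_F = z`.
All rank decisions use SVD with tolerance `max(shape) * eps * σ_max`
(exposed as `rank_tol`). Reported quantities:

* conservation relations `c = m - rank(N)`; dependent rows are kept in `N`
  and never counted as redundancy;
* degrees of freedom `dof = x - rank(N_U)`; determined iff `dof = 0`;
* degrees of redundancy `degR = rank(N) - rank(N_U)`; redundant iff
  `degR > 0`; non-redundant scenarios are always consistent;
* redundancy matrix `R = N_F - N_U N_U^+ N_F`; consistency iff
  `||R r_F||_inf <= consistency_tol`, default `1e-9 * max(1, ||f||_inf)`;
* redundant rates: columns of `R` whose max-magnitude entry exceeds
  `10 * max(m,n) * eps` scaled by the corresponding column norm of `N_F`
  (a pure floating-point-zero threshold);
* determined unknowns: rows of an orthonormal nullspace basis of `N_U`
  (scipy `null_space`) with max entry <= 1e-10.

The reduced redundancy matrix `R_r` keeps the first `degR` rows selected by
QR with column pivoting on `R'`. Any maximal independent row set spans the
same row space and the WLS correction is invariant to the choice; this is
property-tested by mixing `R_r` with random invertible matrices rather than
assumed.

## Correction engines

Sign conventions: WLS/QP use a single signed correction with
`corrected = f - δ`; LP uses paired non-negative slacks with
`corrected = f + δ⁺ - δ⁻`. Reports always show `corrected - given`.

* **WLS** (steady state only): `δ = W R_r'(R_r W R_r')⁻¹ R_r r_F`, `W`
  diagonal with the *reciprocals* `1/w_i`. A pinned rate (infinite weight)
  contributes a zero row of `W` and therefore receives exactly zero
  correction. `R_r W R_r'` with condition number > 1e12 is treated as
  singular and reported as an error.
* **QP**: `min Σ w_i δ_i²` over `(r, δ)` subject to the full constraint
  set. Strictly positive weights make the objective strictly convex in δ,
  so the corrections are unique even when `r` is not.
* **LP**: `min Σ w_i (δ_i⁺ + δ_i⁻)`. At any optimum `min(δ⁺, δ⁻) = 0`
  (otherwise shifting the common part strictly reduces cost); residual
  common mass from the solver is shifted out before reporting. The optional
  uniqueness check pins the objective at its optimum (tolerance
  `1e-9 * max(1,|opt|)`) and minimizes/maximizes every corrected rate over
  the optimal face; `unique` = all ranges below 1e-7.

Weighting schemes: W1 `1/σ_i²` (variances required), W2 `1/|f_i|`, W3 `1`.
Rates fixed at zero get `zero_flux_weight` (default 1e6, floor 1e3) under
W1/W2, or are pinned entirely with `pin_zero_rates`. W2 weights are used
raw, without renormalization.

Both balancers first check the base system (steady state + bounds + general
constraints, no fixed rates) by an LP feasibility solve; if it is already
infeasible the scenario is not correctable through its fixed rates and the
result carries status `infeasible_base` pointing to generalized balancing.
After a QP correction, feasibility of the corrected scenario is re-verified
by an independent LP solve at a relaxed primal tolerance of 1e-6
(configurable): the corrections carry the finite precision of the
optimization, and downstream solves should not be expected to meet 1e-9.

### Generalized slacks

Any subset of {fixed_rates, steady_state, bounds, general} can be selected
for correction. Signed classes (fixed rates, steady-state rows) get one
signed slack under the QP engine and a non-negative pair under the LP
engine; inequality rows (bounds, general) get a single non-negative slack.
Classes not selected stay hard. Per-class slack weights default to 1.0 and
are adjustable; fixed-rate corrections keep the W1–W3 schemes. Feasibility
with the selected slacks free is established by an LP before solving; if
even that fails, the inconsistency lives in an unselected class and a
diagnostic error names the selected targets. With steady-state slacks only,
equal weights, and inconsistencies that are purely algebraic (bounds slack),
the QP slacks coincide with the steady-state residual of the pseudoinverse
solution — both are the Euclidean projection of `z` onto the column space
of `N_U`; this is verified, not assumed, over seeded random scenarios.

## FBA / FVA

FBA and FVA are plain HiGHS LP solves (scipy.optimize.linprog). FVA runs
without fixing the FBA objective — it is applied to the corrected scenario
directly; objective-constrained FVA can be had by adding `c'r >= γ·opt` as
a general constraint. A rate is *determined* when its FVA range width is
<= `det_tol * max(1, |midpoint|)` with `det_tol = 1e-7` by default.
Unbounded directions are reported as ±inf, never as large finite numbers.
The kernel-determined set from classification is always a subset of the
FVA-determined set on a consistent scenario: FVA additionally captures
values forced by irreversibility and bounds.

## The QP solver

No suitable QP library being part of the supported dependency set, the
package ships a dense convex-QP solver (`fluxbalancer._qp`): a Mehrotra
predictor-corrector primal-dual interior-point method (static KKT
regularization 1e-10, fraction-to-boundary 0.995, convergence at residuals
and duality gap <= 1e-10 scaled) followed by an active-set polish that
re-solves the KKT system of the identified active constraints by min-norm
least squares and accepts the polished point only if it is feasible and at
least as good. The polish removes the regularization bias, reaching near
machine precision on the small dense problems that arise here (tens of
variables). The solver assumes feasibility, which callers establish by an
LP phase first. It is cross-checked in the test suite against
scipy's SLSQP on random (including rank-deficient) QPs and against the
closed-form WLS correction.

## Synthetic scenarios

`random_scenario(seed, ...)` emulates desk-scale MFA problems: sparse
random stoichiometries with integer coefficients in {-2,-1,1,2} (about 30%
single-metabolite exchange columns, internal reactions consuming and
producing 2–3 metabolites), default sizes m in [3,8], n in [6,16] chosen to
keep exact rational rank computation and brute-force oracles tractable,
bounds [0,10] (irreversible, default 70%) or [-10,10]. A ground-truth flux
vector is the average of up to four random-objective LP vertices,
re-projected onto the nullspace of `N` (satisfying `N r = 0` and bounds to
<= 1e-8). The fixed subset is drawn at random; per-rate noise sigmas are
drawn in [0.5,1.5]·σ, recorded as variances so the W1 scheme is meaningful.
Default noise σ = 0.1 on fluxes of order 1–10, i.e. a few-percent
measurement error typical of exchange-rate measurements.

What the generator does **not** emulate: genome-scale sparsity patterns and
conditioning, biomass-style columns with hundreds of non-integer
coefficients, correlated measurement errors, and systematic (gross) errors.
Passing tests therefore demonstrate correctness of the algebra and the
optimization contracts at desk scale, not numerical robustness at genome
scale.

## Problem sizes and determinism

The property and recovery suites use 100–300 seeded scenarios of the above
sizes, which keeps each full check within seconds while exceeding the
sample sizes at which the stochastic claims (error reduction with
variance-weighted reconciliation) are stable. All randomness flows through
`numpy.random.default_rng(seed)`; identical seeds give identical scenarios
and byte-identical CLI reports.

## Known limitations

* No gross-error statistical tests (χ² on residuals) on the WLS residuals.
* No cardinality-minimal (MILP) corrections and no irreducibly inconsistent
  subsystem analysis; the redundancy matrix is the only source attribution.
* The LP uniqueness check is exact only up to the objective-pinning
  tolerance; a face of diameter below 1e-7 is reported as unique.
* SBML export is not supported (import only); general constraints `A r <= b`
  exist only in the native JSON dialect.
* The bundled 10-reaction example network is a canonical reconstruction of
  a didactic topology, documented as such; tests assert only its stated
  structural properties.
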