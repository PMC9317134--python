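"""Optimization-based correction of infeasible flux scenarios.

Given a feasible base system (steady state, bounds, general constraints) and
a set of fixed rates that renders it infeasible, two correction engines make
the scenario feasible with minimal changes to the fixed values:

* QP: introduce one signed correction delta_i per fixed rate
  (r_i = f_i - delta_i) and minimize sum_i w_i delta_i^2 subject to the full
  constraint set.  The corrections are unique for strictly positive weights.
* LP: introduce paired non-negative slacks (r_i = f_i + delta_i^+ - delta_i^-)
  and minimize sum_i w_i (delta_i^+ + delta_i^-), the weighted sum of
  absolute changes.  The optimal objective is unique but the corrected
  values may not be; an optional check explores the optimal face.

Generalized balancing extends the same idea to the other constraint classes:
signed (QP) or paired (LP) slacks on steady-state rows, and single
non-negative slacks on bound and general inequality rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._lp import solve_lp
from ._qp import solve_qp
from .exceptions import BalancingError, SolverError
from .model import FluxScenario, MetabolicModel, WeightSpec, as_weight_spec

__all__ = [
    "CorrectionResult",
    "compute_weights",
    "qp_balance",
    "lp_balance",
    "generalized_balance",
    "apply_corrections",
    "check_feasible",
]

#: relaxed primal feasibility tolerance for re-solves on corrected scenarios,
#: which carry the finite precision of the preceding optimization
RELAXED_FEAS_TOL = 1e-6


@dataclass
class CorrectionResult:
    """Outcome of a correction computation.

    ``deltas`` follows the engine's sign convention: for QP/WLS a single
    signed delta with corrected = f - delta; for LP the pair
    (delta_plus, delta_minus) with corrected = f + delta_plus - delta_minus.
    Reports normalise to (corrected - given).
    """

    method: str  # "qp" | "lp" | "wls" | "generalized-qp" | "generalized-lp"
    deltas: dict = field(default_factory=dict)
    corrected_values: dict[str, float] = field(default_factory=dict)
    constraint_slacks: dict | None = None
    objective_value: float = 0.0
    unique: bool | None = None
    status: str = "optimal"  # "optimal" | "infeasible_base" | "solver_failure"
    message: str = ""

    def corrections(self) -> dict[str, float]:
        """Corrections as (corrected - given), independent of engine."""
        out = {}
        for rid, corr in self.corrected_values.items():
            d = self.deltas.get(rid, 0.0)
            given = corr + d if not isinstance(d, tuple) else corr - d[0] + d[1]
            out[rid] = corr - given
        return out


def compute_weights(scenario: FluxScenario, spec: WeightSpec | str) -> dict[str, float]:
    """Per-fixed-rate correction weights w_i for the chosen scheme.

    W1: 1/sigma_i^2 (variances required); W2: 1/|f_i|; W3: 1.  Under W1/W2 a
    rate fixed at zero gets ``spec.zero_flux_weight`` or, with
    ``pin_zero_rates``, an infinite weight (excluded from correction).
    """
    spec = as_weight_spec(spec)
    weights: dict[str, float] = {}
    if spec.scheme == "W1" and scenario.variances is None:
        raise ValueError("weighting scheme W1 requires measurement variances")
    for rid, f in scenario.fixed.items():
        if f == 0.0 and spec.pin_zero_rates:
            weights[rid] = math.inf
            continue
        if spec.scheme == "W1":
            if rid not in (scenario.variances or {}):
                raise ValueError(f"W1: no variance for fixed reaction {rid!r}")
            weights[rid] = 1.0 / scenario.variances[rid]
        elif spec.scheme == "W2":
            weights[rid] = spec.zero_flux_weight if f == 0.0 else 1.0 / abs(f)
        else:
            weights[rid] = 1.0
    return weights


# ---------------------------------------------------------------------------
# feasibility checks


def _bound_rows(model: MetabolicModel):
    """Finite bounds as inequality rows (sign, reaction index, rhs):
    r_i <= ub_i  and  -r_i <= -lb_i."""
    rows = []
    for i in range(model.n_reactions):
        if np.isfinite(model.ub[i]):
            rows.append((+1.0, i, model.ub[i]))
        if np.isfinite(model.lb[i]):
            rows.append((-1.0, i, -model.lb[i]))
    return rows


def check_feasible(
    model: MetabolicModel,
    scenario: FluxScenario | None = None,
    *,
    feasibility_tol: float | None = None,
) -> bool:
    """LP feasibility of steady state + bounds + general constraints
    (+ fixed rates if a scenario is given)."""
    n = model.n_reactions
    A_eq = [model.N]
    b_eq = [np.zeros(model.n_metabolites)]
    if scenario is not None and scenario.fixed:
        scenario.validate(model)
        rows = np.zeros((scenario.k, n))
        vals = np.zeros(scenario.k)
        for j, (rid, f) in enumerate(scenario.fixed.items()):
            rows[j, model.reaction_index(rid)] = 1.0
            vals[j] = f
        A_eq.append(rows)
        b_eq.append(vals)
    res = solve_lp(
        np.zeros(n),
        A_ub=model.A,
        b_ub=model.b,
        A_eq=np.vstack(A_eq),
        b_eq=np.concatenate(b_eq),
        bounds=list(zip(model.lb, model.ub)),
        feasibility_tol=feasibility_tol,
    )
    return res.status == "optimal"


def _split_pins(scenario: FluxScenario, wmap: dict[str, float]):
    """Fixed rates with finite weight get correction variables; infinite
    weight means the rate is pinned (hard equality, no correction)."""
    free = [rid for rid in scenario.fixed if not math.isinf(wmap[rid])]
    pinned = [rid for rid in scenario.fixed if math.isinf(wmap[rid])]
    return free, pinned


def _empty_result(method: str, scenario: FluxScenario) -> CorrectionResult:
    return CorrectionResult(
        method=method,
        deltas={rid: 0.0 for rid in scenario.fixed},
        corrected_values=dict(scenario.fixed),
        objective_value=0.0,
        unique=True,
        status="optimal",
    )


def _infeasible_base(method: str) -> CorrectionResult:
    return CorrectionResult(
        method=method,
        status="infeasible_base",
        message=(
            "the base system (steady state + bounds + general constraints) is "
            "infeasible before any rates are fixed; fixed-rate balancing cannot "
            "help -- use generalized_balance on the offending constraint classes"
        ),
    )


# ---------------------------------------------------------------------------
# QP balancing


def qp_balance(
    model: MetabolicModel,
    scenario: FluxScenario,
    weights: WeightSpec | str | dict[str, float] = "W3",
    *,
    verify_tol: float = RELAXED_FEAS_TOL,
) -> CorrectionResult:
    """Minimal weighted squared corrections of the fixed rates (QP).

    Solves min sum_i w_i delta_i^2 subject to steady state, bounds, general
    constraints and r_i = f_i - delta_i.  The deltas are unique at the
    optimum for strictly positive weights.  The corrected scenario is
    re-verified feasible by an independent LP solve at ``verify_tol``.
    """
    scenario.validate(model)
    if not scenario.fixed:
        return _empty_result("qp", scenario)
    if not check_feasible(model):
        return _infeasible_base("qp")
    wmap = weights if isinstance(weights, dict) else compute_weights(scenario, weights)
    if any((not math.isinf(w)) and w <= 0 for w in wmap.values()):
        raise ValueError("correction weights must be strictly positive")
    free, pinned = _split_pins(scenario, wmap)

    n = model.n_reactions
    kf = len(free)
    dim = n + kf
    P = np.zeros((dim, dim))
    for j, rid in enumerate(free):
        P[n + j, n + j] = 2.0 * wmap[rid]
    q = np.zeros(dim)

    # equalities: N r = 0 ; r_i + delta_i = f_i (free) ; r_i = f_i (pinned)
    m = model.n_metabolites
    E = np.zeros((m + kf + len(pinned), dim))
    e = np.zeros(m + kf + len(pinned))
    E[:m, :n] = model.N
    for j, rid in enumerate(free):
        i = model.reaction_index(rid)
        E[m + j, i] = 1.0
        E[m + j, n + j] = 1.0
        e[m + j] = scenario.fixed[rid]
    for j, rid in enumerate(pinned):
        E[m + kf + j, model.reaction_index(rid)] = 1.0
        e[m + kf + j] = scenario.fixed[rid]

    # inequalities: finite bounds on r, plus A r <= b
    G_rows, h_vals = [], []
    for sign, i, rhs in _bound_rows(model):
        row = np.zeros(dim)
        row[i] = sign
        G_rows.append(row)
        h_vals.append(rhs)
    if model.A is not None:
        G_rows.extend(np.hstack([model.A, np.zeros((model.A.shape[0], kf))]))
        h_vals.extend(model.b)
    G = np.vstack(G_rows) if G_rows else None
    h = np.array(h_vals) if G_rows else None

    res = solve_qp(P, q, E, e, G, h)
    delta = {rid: float(res.x[n + j]) for j, rid in enumerate(free)}
    delta.update({rid: 0.0 for rid in pinned})
    corrected = {rid: scenario.fixed[rid] - delta[rid] for rid in scenario.fixed}
    obj = sum(wmap[rid] * delta[rid] ** 2 for rid in free)

    out = CorrectionResult(
        method="qp",
        deltas=delta,
        corrected_values=corrected,
        objective_value=obj,
        unique=True,
        status="optimal",
    )
    corrected_scen = FluxScenario(fixed=corrected, variances=scenario.variances)
    if res.status != "optimal" or not check_feasible(
        model, corrected_scen, feasibility_tol=verify_tol
    ):
        out.status = "solver_failure"
        out.message = f"QP did not produce a verifiably feasible correction ({res.status})"
    return out


# ---------------------------------------------------------------------------
# LP balancing


def lp_balance(
    model: MetabolicModel,
    scenario: FluxScenario,
    weights: WeightSpec | str | dict[str, float] = "W3",
    *,
    check_uniqueness: bool = False,
    uniqueness_tol: float = 1e-7,
) -> CorrectionResult:
    """Minimal weighted absolute corrections of the fixed rates (LP).

    Solves min sum_i w_i (delta_i^+ + delta_i^-) with paired non-negative
    slacks and r_i = f_i + delta_i^+ - delta_i^-.  At any optimum at least
    one of each slack pair is zero.  The objective value is unique; the
    corrected values may not be -- with ``check_uniqueness`` the optimal face
    is explored by minimizing/maximizing each corrected rate at fixed
    objective value.
    """
    scenario.validate(model)
    if not scenario.fixed:
        return _empty_result("lp", scenario)
    if not check_feasible(model):
        return _infeasible_base("lp")
    wmap = weights if isinstance(weights, dict) else compute_weights(scenario, weights)
    if any((not math.isinf(w)) and w <= 0 for w in wmap.values()):
        raise ValueError("correction weights must be strictly positive")
    free, pinned = _split_pins(scenario, wmap)

    n = model.n_reactions
    kf = len(free)
    dim = n + 2 * kf  # [r, delta+, delta-]

    c = np.zeros(dim)
    for j, rid in enumerate(free):
        c[n + j] = wmap[rid]
        c[n + kf + j] = wmap[rid]

    m = model.n_metabolites
    A_eq = np.zeros((m + kf + len(pinned), dim))
    b_eq = np.zeros(m + kf + len(pinned))
    A_eq[:m, :n] = model.N
    for j, rid in enumerate(free):
        i = model.reaction_index(rid)
        A_eq[m + j, i] = 1.0
        A_eq[m + j, n + j] = -1.0
        A_eq[m + j, n + kf + j] = 1.0
        b_eq[m + j] = scenario.fixed[rid]
    for j, rid in enumerate(pinned):
        A_eq[m + kf + j, model.reaction_index(rid)] = 1.0
        b_eq[m + kf + j] = scenario.fixed[rid]

    A_ub = None
    b_ub = None
    if model.A is not None:
        A_ub = np.hstack([model.A, np.zeros((model.A.shape[0], 2 * kf))])
        b_ub = model.b
    bounds = list(zip(model.lb, model.ub)) + [(0.0, None)] * (2 * kf)

    res = solve_lp(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
    if res.status != "optimal":
        return CorrectionResult(method="lp", status="solver_failure", message=res.status)

    dplus = res.x[n : n + kf].copy()
    dminus = res.x[n + kf :].copy()
    # any common mass in a pair is cost without effect; shift it out
    common = np.minimum(dplus, dminus)
    dplus -= common
    dminus -= common

    deltas: dict = {rid: (float(dplus[j]), float(dminus[j])) for j, rid in enumerate(free)}
    deltas.update({rid: (0.0, 0.0) for rid in pinned})
    corrected = {
        rid: scenario.fixed[rid] + deltas[rid][0] - deltas[rid][1] for rid in scenario.fixed
    }
    obj = float(sum(wmap[rid] * (dp + dm) for rid, (dp, dm) in deltas.items() if rid in set(free)))

    unique: bool | None = None
    if check_uniqueness:
        unique = _lp_uniqueness(
            c, A_ub, b_ub, A_eq, b_eq, bounds, res.objective, model, free, uniqueness_tol
        )

    return CorrectionResult(
        method="lp",
        deltas=deltas,
        corrected_values=corrected,
        objective_value=obj,
        unique=unique,
        status="optimal",
    )


def _lp_uniqueness(c, A_ub, b_ub, A_eq, b_eq, bounds, opt, model, free, tol) -> bool:
    """Range of every corrected rate over the optimal face (objective pinned
    at its optimum)."""
    row = c.reshape(1, -1)
    A_ub2 = row if A_ub is None else np.vstack([A_ub, row])
    b_ub2 = np.array([opt + 1e-9 * max(1.0, abs(opt))])
    if b_ub is not None:
        b_ub2 = np.concatenate([b_ub, b_ub2])
    for rid in free:
        i = model.reaction_index(rid)
        obj = np.zeros(len(c))
        obj[i] = 1.0
        lo = solve_lp(obj, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        hi = solve_lp(-obj, A_ub=A_ub2, b_ub=b_ub2, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        if lo.status != "optimal" or hi.status != "optimal":
            return False
        if (-hi.objective) - lo.objective > tol * max(1.0, abs(lo.objective)):
            return False
    return True


# ---------------------------------------------------------------------------
# generalized slack balancing


_TARGET_CLASSES = ("fixed_rates", "steady_state", "bounds", "general")


def generalized_balance(
    model: MetabolicModel,
    scenario: FluxScenario,
    targets=("fixed_rates",),
    weights: WeightSpec | str | dict[str, float] = "W3",
    *,
    engine: str = "qp",
    slack_weights: dict[str, float] | None = None,
) -> CorrectionResult:
    """Minimal corrections with slacks on arbitrary constraint classes.

    ``targets`` selects which constraint classes may be relaxed:
    ``fixed_rates`` (corrections of the fixed values, as in qp/lp_balance),
    ``steady_state`` (signed slack per metabolite row, N r = s), ``bounds``
    (non-negative slacks widening finite bounds) and ``general`` (non-negative
    slack per row of A r <= b).  Constraint classes not selected stay hard.

    ``weights`` applies to fixed-rate corrections; ``slack_weights`` maps the
    other class names to a positive scalar weight (default 1.0 each).  The
    objective is the weighted sum of squared (QP) or absolute (LP) slacks.
    """
    scenario.validate(model)
    targets = set(targets)
    if not targets:
        raise ValueError("at least one slack target class must be selected")
    unknown = targets - set(_TARGET_CLASSES)
    if unknown:
        raise ValueError(f"unknown slack target class(es): {sorted(unknown)}")
    if engine not in {"qp", "lp"}:
        raise ValueError("engine must be 'qp' or 'lp'")
    sw = {cls: 1.0 for cls in _TARGET_CLASSES}
    sw.update(slack_weights or {})

    n = model.n_reactions
    m = model.n_metabolites
    fixed_ids = list(scenario.fixed)
    if "fixed_rates" in targets and fixed_ids:
        wmap = weights if isinstance(weights, dict) else compute_weights(scenario, weights)
        free, pinned = _split_pins(scenario, wmap)
    else:
        wmap, free, pinned = {}, [], fixed_ids

    bound_rows = _bound_rows(model) if "bounds" in targets else []
    hard_bounds = "bounds" not in targets
    p_general = 0 if model.A is None else model.A.shape[0]
    slack_general = p_general if "general" in targets else 0
    slack_steady = m if "steady_state" in targets else 0

    # variable layout: r (n) | fixed-rate slack(s) | steady slack(s) |
    #                  bound slacks | general slacks
    # signed classes (fixed_rates, steady_state) use 1 var under QP, 2 under LP
    signed_width = 1 if engine == "qp" else 2
    kf = len(free)
    n_fix = kf * signed_width
    n_ss = slack_steady * signed_width
    n_bnd = len(bound_rows)
    dim = n + n_fix + n_ss + n_bnd + slack_general
    off_fix, off_ss = n, n + n_fix
    off_bnd = off_ss + n_ss
    off_gen = off_bnd + n_bnd

    # --- constraint assembly (shared by feasibility precheck and solve) ---
    eq_rows, eq_rhs = [], []
    # steady state rows: N r - s = 0  (s absent -> hard)
    for i in range(m):
        row = np.zeros(dim)
        row[:n] = model.N[i]
        if slack_steady:
            if engine == "qp":
                row[off_ss + i] = -1.0
            else:
                row[off_ss + 2 * i] = -1.0
                row[off_ss + 2 * i + 1] = 1.0
        eq_rows.append(row)
        eq_rhs.append(0.0)
    # fixed rates
    for j, rid in enumerate(free):
        row = np.zeros(dim)
        row[model.reaction_index(rid)] = 1.0
        if engine == "qp":  # r + delta = f
            row[off_fix + j] = 1.0
        else:  # r - d+ + d- = f
            row[off_fix + 2 * j] = -1.0
            row[off_fix + 2 * j + 1] = 1.0
        eq_rows.append(row)
        eq_rhs.append(scenario.fixed[rid])
    for rid in pinned:
        row = np.zeros(dim)
        row[model.reaction_index(rid)] = 1.0
        eq_rows.append(row)
        eq_rhs.append(scenario.fixed[rid])

    ub_rows, ub_rhs = [], []
    if "bounds" in targets:
        # sign * r_i - t <= rhs, t >= 0
        for jj, (sign, i, rhs) in enumerate(bound_rows):
            row = np.zeros(dim)
            row[i] = sign
            row[off_bnd + jj] = -1.0
            ub_rows.append(row)
            ub_rhs.append(rhs)
    if model.A is not None:
        for i in range(p_general):
            row = np.zeros(dim)
            row[:n] = model.A[i]
            if slack_general:
                row[off_gen + i] = -1.0
            ub_rows.append(row)
            ub_rhs.append(model.b[i])

    r_bounds = (
        [(None, None)] * n if not hard_bounds else list(zip(model.lb, model.ub))
    )
    var_bounds = list(r_bounds)
    var_bounds += [(None, None)] * n_fix if engine == "qp" else [(0.0, None)] * n_fix
    var_bounds += [(None, None)] * n_ss if engine == "qp" else [(0.0, None)] * n_ss
    var_bounds += [(0.0, None)] * (n_bnd + slack_general)
    if engine == "lp":
        var_bounds[n : n + n_fix] = [(0.0, None)] * n_fix
        var_bounds[off_ss : off_ss + n_ss] = [(0.0, None)] * n_ss

    A_eq = np.vstack(eq_rows) if eq_rows else None
    b_eq = np.array(eq_rhs) if eq_rows else None
    A_ub = np.vstack(ub_rows) if ub_rows else None
    b_ub = np.array(ub_rhs) if ub_rows else None

    # feasibility with the selected slacks free
    feas = solve_lp(np.zeros(dim), A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds)
    if feas.status != "optimal":
        raise BalancingError(
            "system remains infeasible with the selected slack targets "
            f"{sorted(targets)}; the inconsistency involves a constraint class "
            "that was not selected for correction"
        )

    # weights per slack variable
    w_fix = np.array([wmap[rid] for rid in free], dtype=float) if free else np.zeros(0)

    if engine == "qp":
        P = np.zeros((dim, dim))
        for j in range(kf):
            P[off_fix + j, off_fix + j] = 2.0 * w_fix[j]
        for i in range(slack_steady):
            P[off_ss + i, off_ss + i] = 2.0 * sw["steady_state"]
        for jj in range(n_bnd):
            P[off_bnd + jj, off_bnd + jj] = 2.0 * sw["bounds"]
        for i in range(slack_general):
            P[off_gen + i, off_gen + i] = 2.0 * sw["general"]
        G_rows, h_vals = [], []
        if A_ub is not None:
            G_rows.append(A_ub)
            h_vals.append(b_ub)
        for i, (lo, hi) in enumerate(var_bounds):
            if lo is not None and np.isfinite(lo):
                row = np.zeros(dim)
                row[i] = -1.0
                G_rows.append(row.reshape(1, -1))
                h_vals.append(np.array([-lo]))
            if hi is not None and np.isfinite(hi):
                row = np.zeros(dim)
                row[i] = 1.0
                G_rows.append(row.reshape(1, -1))
                h_vals.append(np.array([hi]))
        G = np.vstack(G_rows) if G_rows else None
        h = np.concatenate(h_vals) if G_rows else None
        res = solve_qp(P, np.zeros(dim), A_eq, b_eq, G, h)
        if res.status != "optimal":
            raise SolverError("generalized QP balancing did not converge")
        xopt = res.x
        obj = 0.5 * float(xopt @ P @ xopt)
    else:
        cvec = np.zeros(dim)
        cvec[off_fix : off_fix + n_fix] = np.repeat(w_fix, 2) if kf else []
        cvec[off_ss : off_ss + n_ss] = sw["steady_state"]
        cvec[off_bnd : off_bnd + n_bnd] = sw["bounds"]
        cvec[off_gen : off_gen + slack_general] = sw["general"]
        res = solve_lp(cvec, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=var_bounds)
        if res.status != "optimal":
            raise SolverError(f"generalized LP balancing failed: {res.status}")
        xopt = res.x
        obj = float(res.objective)

    # unpack
    deltas: dict = {}
    corrected = dict(scenario.fixed)
    for j, rid in enumerate(free):
        if engine == "qp":
            d = float(xopt[off_fix + j])
            deltas[rid] = d
            corrected[rid] = scenario.fixed[rid] - d
        else:
            dp = float(xopt[off_fix + 2 * j])
            dm = float(xopt[off_fix + 2 * j + 1])
            c2 = min(dp, dm)
            deltas[rid] = (dp - c2, dm - c2)
            corrected[rid] = scenario.fixed[rid] + dp - dm
    for rid in pinned:
        deltas[rid] = 0.0 if engine == "qp" else (0.0, 0.0)

    slacks: dict = {}
    if slack_steady:
        vals = []
        for i in range(m):
            if engine == "qp":
                vals.append(float(xopt[off_ss + i]))
            else:
                vals.append(float(xopt[off_ss + 2 * i] - xopt[off_ss + 2 * i + 1]))
        slacks["steady_state"] = dict(zip(model.metabolite_ids, vals))
    if n_bnd:
        lbs: dict[str, float] = {}
        ubs: dict[str, float] = {}
        for jj, (sign, i, _) in enumerate(bound_rows):
            val = float(xopt[off_bnd + jj])
            (ubs if sign > 0 else lbs)[model.reaction_ids[i]] = val
        slacks["ub"] = ubs
        slacks["lb"] = lbs
    if slack_general:
        slacks["general"] = [float(v) for v in xopt[off_gen : off_gen + slack_general]]

    return CorrectionResult(
        method=f"generalized-{engine}",
        deltas=deltas,
        corrected_values=corrected,
        constraint_slacks=slacks or None,
        objective_value=obj,
        unique=True if engine == "qp" else None,
        status="optimal",
    )


def apply_corrections(scenario: FluxScenario, result: CorrectionResult) -> FluxScenario:
    """New scenario with the corrected fixed values; the input is unchanged."""
    if result.status != "optimal":
        raise ValueError(f"cannot apply corrections with status {result.status!r}")
    fixed = dict(scenario.fixed)
    fixed.update(result.corrected_values)
    return FluxScenario(fixed=fixed, variances=scenario.variances)
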