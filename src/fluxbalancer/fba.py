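"""Flux balance analysis and flux variability analysis.

FBA maximizes (or minimizes) a linear objective c'r over the flux polyhedron
{N r = 0, lb <= r <= ub, A r <= b, r_F = f}.  FVA minimizes and maximizes
every individual flux over the same polyhedron (without the FBA objective
fixed), which identifies the rates uniquely determined by a (corrected)
scenario: those whose minimum and maximum coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._lp import solve_lp
from .exceptions import InfeasibleScenarioError, ModelError
from .model import FluxScenario, MetabolicModel

__all__ = ["FBAResult", "FVAResult", "fba", "fva", "determined_rates"]

DEFAULT_DET_TOL = 1e-7


@dataclass
class FBAResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: float | None
    fluxes: dict[str, float] | None


@dataclass
class FVAResult:
    """Per-reaction flux ranges; a rate is *determined* when its range has
    collapsed to a point (width <= det_tol * max(1, |value|))."""

    ranges: dict[str, tuple[float, float]]
    det_tol: float = DEFAULT_DET_TOL
    determined: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.determined:
            for rid, (lo, hi) in self.ranges.items():
                if not (np.isfinite(lo) and np.isfinite(hi)):
                    self.determined[rid] = False
                else:
                    mid = 0.5 * (lo + hi)
                    self.determined[rid] = (hi - lo) <= self.det_tol * max(1.0, abs(mid))


def _scenario_eq(model: MetabolicModel, scenario: FluxScenario | None):
    A_eq = [model.N]
    b_eq = [np.zeros(model.n_metabolites)]
    if scenario is not None and scenario.fixed:
        scenario.validate(model)
        rows = np.zeros((scenario.k, model.n_reactions))
        vals = np.zeros(scenario.k)
        for j, (rid, f) in enumerate(scenario.fixed.items()):
            rows[j, model.reaction_index(rid)] = 1.0
            vals[j] = f
        A_eq.append(rows)
        b_eq.append(vals)
    return np.vstack(A_eq), np.concatenate(b_eq)


def fba(
    model: MetabolicModel,
    scenario: FluxScenario | None = None,
    sense: str = "max",
    objective: np.ndarray | dict[str, float] | None = None,
    *,
    feasibility_tol: float | None = None,
) -> FBAResult:
    """Solve the FBA linear program max/min c'r over the constrained fluxes."""
    if objective is None:
        if model.objective_c is None:
            raise ModelError("model has no objective and none was supplied")
        c = model.objective_c.copy()
    elif isinstance(objective, dict):
        c = np.zeros(model.n_reactions)
        for rid, coef in objective.items():
            c[model.reaction_index(rid)] = coef
    else:
        c = np.asarray(objective, dtype=float).ravel()
    if sense not in {"max", "min"}:
        raise ValueError("sense must be 'max' or 'min'")
    sign = -1.0 if sense == "max" else 1.0

    A_eq, b_eq = _scenario_eq(model, scenario)
    res = solve_lp(
        sign * c,
        A_ub=model.A,
        b_ub=model.b,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=list(zip(model.lb, model.ub)),
        feasibility_tol=feasibility_tol,
    )
    if res.status != "optimal":
        return FBAResult(status=res.status, objective_value=None, fluxes=None)
    return FBAResult(
        status="optimal",
        objective_value=float(c @ res.x),
        fluxes=dict(zip(model.reaction_ids, (float(v) for v in res.x))),
    )


def fva(
    model: MetabolicModel,
    scenario: FluxScenario | None = None,
    reactions: list[str] | None = None,
    *,
    det_tol: float = DEFAULT_DET_TOL,
    feasibility_tol: float | None = None,
) -> FVAResult:
    """Per-reaction [min, max] flux ranges over the (fixed-rate) polyhedron.

    Raises InfeasibleScenarioError when the scenario admits no flux vector;
    balance the scenario first.  Unbounded directions are reported as +-inf.
    """
    ids = list(model.reaction_ids) if reactions is None else list(reactions)
    for rid in ids:
        model.reaction_index(rid)
    A_eq, b_eq = _scenario_eq(model, scenario)
    bounds = list(zip(model.lb, model.ub))

    probe = solve_lp(
        np.zeros(model.n_reactions),
        A_ub=model.A,
        b_ub=model.b,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        feasibility_tol=feasibility_tol,
    )
    if probe.status != "optimal":
        raise InfeasibleScenarioError(
            "scenario is infeasible; balance it (qp_balance/lp_balance) before FVA"
        )

    ranges: dict[str, tuple[float, float]] = {}
    for rid in ids:
        i = model.reaction_index(rid)
        c = np.zeros(model.n_reactions)
        c[i] = 1.0
        extremes = []
        for sign in (1.0, -1.0):
            res = solve_lp(
                sign * c,
                A_ub=model.A,
                b_ub=model.b,
                A_eq=A_eq,
                b_eq=b_eq,
                bounds=bounds,
                feasibility_tol=feasibility_tol,
            )
            if res.status == "unbounded":
                extremes.append(sign * -np.inf if sign < 0 else -np.inf)
                # min unbounded -> -inf; max unbounded -> +inf
                extremes[-1] = -np.inf if sign > 0 else np.inf
            else:
                extremes.append(float(res.x[i]))
        lo, hi = extremes
        if lo > hi:  # numerical jitter on degenerate ranges
            lo, hi = hi, lo
        ranges[rid] = (lo, hi)
    return FVAResult(ranges=ranges, det_tol=det_tol)


def determined_rates(result: FVAResult) -> set[str]:
    """Reactions whose FVA range collapsed to a single value."""
    return {rid for rid, flag in result.determined.items() if flag}
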