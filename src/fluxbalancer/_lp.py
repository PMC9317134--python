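"""Thin wrapper around scipy's HiGHS linear programming interface."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .exceptions import SolverError

__all__ = ["LPResult", "solve_lp"]

#: scipy.optimize status codes
_OPTIMAL, _ITER, _INFEASIBLE, _UNBOUNDED, _NUMERICAL = 0, 1, 2, 3, 4


@dataclass
class LPResult:
    status: str  # "optimal" | "infeasible" | "unbounded"
    x: np.ndarray | None
    objective: float | None


def solve_lp(
    c: np.ndarray,
    A_ub: np.ndarray | None = None,
    b_ub: np.ndarray | None = None,
    A_eq: np.ndarray | None = None,
    b_eq: np.ndarray | None = None,
    bounds=None,
    *,
    feasibility_tol: float | None = None,
) -> LPResult:
    """Minimize ``c @ x``; raise SolverError on solver breakdown.

    ``feasibility_tol`` loosens the HiGHS primal feasibility tolerance; used
    when re-solving corrected scenarios whose fixed values carry the finite
    precision of a previous optimization.
    """
    options: dict = {"presolve": True}
    if feasibility_tol is not None:
        options["primal_feasibility_tolerance"] = feasibility_tol
        options["dual_feasibility_tolerance"] = max(feasibility_tol, 1e-9)
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options=options,
    )
    if res.status == _OPTIMAL:
        return LPResult("optimal", np.asarray(res.x, dtype=float), float(res.fun))
    if res.status == _INFEASIBLE:
        return LPResult("infeasible", None, None)
    if res.status == _UNBOUNDED:
        return LPResult("unbounded", None, None)
    raise SolverError(f"LP solver failure (status {res.status}): {res.message}")
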