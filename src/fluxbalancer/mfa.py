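"""Classical metabolic flux analysis on the steady-state system alone.

Fixing the rates of a reaction subset ``F`` splits the steady-state system
``N r = 0`` into

    N_U r_U = -N_F r_F = z,

a linear system in the unknown rates ``r_U``.  Its two key properties are

* determinacy: rank(N_U) = x (= |U|) means every unknown rate is uniquely
  calculable; otherwise the scenario is underdetermined with
  dof = x - rank(N_U) degrees of freedom, and the uniquely determined
  unknowns are exactly those whose row in a nullspace basis of N_U is zero;
* redundancy: fixing rates may create new row dependencies,
  degR = rank(N) - rank(N_U) > 0.  Redundant scenarios are consistent only
  if the fixed values satisfy R r_F = 0, where

      R = N_F - N_U N_U^+ N_F

  is the redundancy matrix (N_U^+ the Moore-Penrose pseudoinverse).  The
  non-zero columns of R mark the fixed rates involved in the redundancy.

Inconsistent scenarios can be reconciled analytically: with a diagonal
matrix W holding the *reciprocals* of the correction weights w_i, the
weighted least-squares correction

    delta = W Rr' (Rr W Rr')^{-1} Rr r_F,      corrected r_F = f - delta,

(Rr = a maximal independent row set of R) minimizes sum_i w_i delta_i^2
subject to steady state.  Conservation relations (rank-deficient N) are
supported throughout; dependent rows never count towards redundancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .balancing import CorrectionResult, compute_weights
from .exceptions import SolverError
from .model import FluxScenario, MetabolicModel, WeightSpec, as_weight_spec

__all__ = [
    "Partition",
    "ScenarioDiagnosis",
    "partition",
    "diagnose",
    "redundancy_matrix",
    "reduced_redundancy_matrix",
    "pseudoinverse_solution",
    "wls_correction",
    "numerical_rank",
]


def numerical_rank(M: np.ndarray, rank_tol: float | None = None) -> int:
    """Numerical rank via SVD; default tolerance max(shape)*eps*sigma_max."""
    M = np.atleast_2d(M)
    if M.size == 0:
        return 0
    sv = scipy.linalg.svdvals(M)
    if rank_tol is None:
        rank_tol = max(M.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0)
    return int(np.sum(sv > rank_tol))


@dataclass
class Partition:
    """Split of the stoichiometric system into unknown and fixed parts."""

    model: MetabolicModel
    scenario: FluxScenario
    U: list[int]  # indices of unknown-rate reactions, model order
    F: list[int]  # indices of fixed-rate reactions, model order
    NU: np.ndarray  # m x x
    NF: np.ndarray  # m x k
    rF: np.ndarray  # fixed values aligned with F
    z: np.ndarray  # z = -NF @ rF

    @property
    def unknown_ids(self) -> list[str]:
        return [self.model.reaction_ids[i] for i in self.U]

    @property
    def fixed_ids(self) -> list[str]:
        return [self.model.reaction_ids[i] for i in self.F]


def partition(model: MetabolicModel, scenario: FluxScenario) -> Partition:
    scenario.validate(model)
    fixed_idx = sorted(model.reaction_index(rid) for rid in scenario.fixed)
    fset = set(fixed_idx)
    unknown_idx = [i for i in range(model.n_reactions) if i not in fset]
    NU = model.N[:, unknown_idx]
    NF = model.N[:, fixed_idx]
    rF = np.array([scenario.fixed[model.reaction_ids[i]] for i in fixed_idx], dtype=float)
    z = -NF @ rF if fixed_idx else np.zeros(model.n_metabolites)
    return Partition(model, scenario, unknown_idx, fixed_idx, NU, NF, rF, z)


def redundancy_matrix(part: Partition) -> np.ndarray:
    """R = NF - NU NU^+ NF (m x k); zero matrix iff the scenario adds no
    new row dependencies."""
    if not part.F:
        return np.zeros((part.model.n_metabolites, 0))
    if part.NU.shape[1] == 0:
        return part.NF.copy()
    return part.NF - part.NU @ (np.linalg.pinv(part.NU) @ part.NF)


def reduced_redundancy_matrix(R: np.ndarray, degR: int, rank_tol: float | None = None) -> np.ndarray:
    """A maximal set of ``degR`` linearly independent rows of R.

    Row selection uses QR with column pivoting on R'; any independent row
    set spans the same row space, and the weighted least-squares correction
    is invariant to the choice.
    """
    if degR == 0:
        return np.zeros((0, R.shape[1]))
    _, _, piv = scipy.linalg.qr(R.T, pivoting=True, mode="economic")
    return R[np.sort(piv[:degR])]


@dataclass
class ScenarioDiagnosis:
    """Determinacy / redundancy / consistency classification of a scenario."""

    rank_N: int
    rank_NU: int
    c: int  # independent conservation relations, m - rank(N)
    dof: int  # degrees of freedom, x - rank(NU)
    degR: int  # degrees of redundancy, rank(N) - rank(NU)
    determinacy: str  # "determined" | "underdetermined"
    redundancy: str  # "redundant" | "non-redundant"
    consistency: str  # "consistent" | "inconsistent"
    redundancy_matrix: np.ndarray
    reduced_redundancy_matrix: np.ndarray
    redundant_rate_ids: list[str]
    residual: np.ndarray  # R @ rF
    determined_unknowns: list[str]
    fixed_ids: list[str] = field(default_factory=list)
    rank_tol: float | None = None
    consistency_tol: float | None = None

    def summary(self) -> str:
        lines = [
            f"determinacy:   {self.determinacy} (dof = {self.dof})",
            f"redundancy:    {self.redundancy} (degR = {self.degR})",
            f"consistency:   {self.consistency}"
            + (f" (max |R rF| = {np.abs(self.residual).max():.3g})" if self.degR else ""),
            f"conservation relations: {self.c}",
        ]
        if self.redundant_rate_ids:
            lines.append("redundant rates: " + ", ".join(self.redundant_rate_ids))
        if self.determined_unknowns:
            lines.append("uniquely determined unknowns: " + ", ".join(self.determined_unknowns))
        return "\n".join(lines)


def diagnose(
    model: MetabolicModel,
    scenario: FluxScenario,
    *,
    rank_tol: float | None = None,
    consistency_tol: float | None = None,
) -> ScenarioDiagnosis:
    """Full rank/redundancy/consistency diagnosis of a flux scenario."""
    part = partition(model, scenario)
    x = len(part.U)
    rank_N = numerical_rank(model.N, rank_tol)
    rank_NU = numerical_rank(part.NU, rank_tol) if x else 0
    c = model.n_metabolites - rank_N
    dof = x - rank_NU
    degR = rank_N - rank_NU

    R = redundancy_matrix(part)
    Rr = reduced_redundancy_matrix(R, degR, rank_tol)
    residual = R @ part.rF if part.F else np.zeros(model.n_metabolites)

    if consistency_tol is None:
        fmax = np.abs(part.rF).max(initial=0.0)
        consistency_tol = 1e-9 * max(1.0, fmax)
    consistent = np.abs(residual).max(initial=0.0) <= consistency_tol

    # fixed rates involved in redundancies: non-zero columns of R, with a
    # floating-point threshold scaled by the corresponding column of NF
    redundant_ids: list[str] = []
    if part.F and degR > 0:
        col_scale = np.maximum(1.0, np.linalg.norm(part.NF, axis=0))
        thr = 10 * max(model.N.shape) * np.finfo(float).eps
        for j, rid in enumerate(part.fixed_ids):
            if np.abs(R[:, j]).max() > thr * col_scale[j]:
                redundant_ids.append(rid)

    determined: list[str] = []
    if x:
        KU = scipy.linalg.null_space(part.NU)
        if KU.shape[1] == 0:
            determined = list(part.unknown_ids)
        else:
            row_norm = np.abs(KU).max(axis=1)
            determined = [part.unknown_ids[i] for i in np.nonzero(row_norm <= 1e-10)[0]]

    return ScenarioDiagnosis(
        rank_N=rank_N,
        rank_NU=rank_NU,
        c=c,
        dof=dof,
        degR=degR,
        determinacy="determined" if rank_NU == x else "underdetermined",
        redundancy="redundant" if degR > 0 else "non-redundant",
        consistency="consistent" if consistent else "inconsistent",
        redundancy_matrix=R,
        reduced_redundancy_matrix=Rr,
        redundant_rate_ids=redundant_ids,
        residual=residual,
        determined_unknowns=determined,
        fixed_ids=part.fixed_ids,
        rank_tol=rank_tol,
        consistency_tol=consistency_tol,
    )


def pseudoinverse_solution(part: Partition) -> np.ndarray:
    """Least-squares solution r_U = N_U^+ z of the partitioned system.

    Minimizes ||N_U r_U - z||_2; among all least-squares solutions it is the
    one of minimal Euclidean norm.  Only the unknowns flagged as determined
    (zero rows of a nullspace basis of N_U) are unique.  Returns an empty
    vector when every rate is fixed.
    """
    if part.NU.shape[1] == 0:
        return np.zeros(0)
    return np.linalg.pinv(part.NU) @ part.z


def wls_correction(
    part: Partition,
    diag: ScenarioDiagnosis,
    weights: WeightSpec | dict[str, float] | str = "W3",
) -> CorrectionResult:
    """Analytical weighted least-squares correction of the fixed rates.

    Implements delta = W Rr' (Rr W Rr')^{-1} Rr r_F with W holding the
    reciprocal weights 1/w_i on its diagonal; corrected rates are f - delta
    and satisfy Rr (f - delta) = 0.  Fixed rates not involved in any
    redundancy are never corrected.  With degR = 0 all corrections are zero.
    """
    fixed_ids = part.fixed_ids
    if isinstance(weights, dict):
        wmap = {rid: float(weights[rid]) for rid in fixed_ids}
    else:
        wmap = compute_weights(part.scenario, as_weight_spec(weights))
    w = np.array([wmap[rid] for rid in fixed_ids], dtype=float)
    if np.any(w <= 0):
        raise ValueError("correction weights must be strictly positive")

    if diag.degR == 0 or not fixed_ids:
        corrected = dict(zip(fixed_ids, part.rF))
        return CorrectionResult(
            method="wls",
            deltas={rid: 0.0 for rid in fixed_ids},
            corrected_values=corrected,
            objective_value=0.0,
            unique=True,
            status="optimal",
        )

    # infinite weight = pinned rate = zero row in W
    Winv_diag = np.where(np.isinf(w), 0.0, 1.0 / w)
    Rr = diag.reduced_redundancy_matrix
    M = Rr * Winv_diag @ Rr.T  # Rr W Rr'
    rhs = Rr @ part.rF
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e12:
        raise SolverError(
            "Rr W Rr' is numerically singular; offending redundancy rows: "
            f"{[int(i) for i in range(Rr.shape[0])]} (check weights/pins)"
        )
    delta = Winv_diag * (Rr.T @ np.linalg.solve(M, rhs))
    corrected = part.rF - delta
    obj = float(np.sum(np.where(np.isinf(w), 0.0, w) * delta**2))
    return CorrectionResult(
        method="wls",
        deltas=dict(zip(fixed_ids, delta)),
        corrected_values=dict(zip(fixed_ids, corrected)),
        objective_value=obj,
        unique=True,
        status="optimal",
    )
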