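"""Core data containers: metabolic model, flux scenario, correction weighting.

A metabolic network with ``m`` metabolites and ``n`` reactions is represented
by its stoichiometric matrix ``N`` (m x n).  A steady-state flux vector ``r``
satisfies ``N r = 0`` together with per-reaction bounds ``lb <= r <= ub`` and,
optionally, general linear inequality constraints ``A r <= b`` (e.g. enzyme
capacity limits) and a linear FBA objective ``c``.

A *flux scenario* clamps a subset ``F`` of reactions to known (typically
measured) values ``r_i = f_i``; optional measurement variances feed the
1/sigma^2 weighting scheme used when inconsistent scenarios are balanced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import ModelError, ScenarioError

__all__ = ["MetabolicModel", "FluxScenario", "WeightSpec"]


@dataclass
class MetabolicModel:
    """Stoichiometric model with bounds, optional constraints and objective.

    Parameters
    ----------
    reaction_ids, metabolite_ids
        Ordered unique identifiers (columns and rows of ``N``).
    N
        Stoichiometric coefficient matrix, shape ``(m, n)``.
    lb, ub
        Flux bounds per reaction; ``+-inf`` allowed.
    A, b
        Optional general inequality constraints ``A r <= b`` (``A`` is p x n).
    objective_c
        Optional linear objective coefficients (length n).
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    N: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    A: np.ndarray | None = None
    b: np.ndarray | None = None
    objective_c: np.ndarray | None = None
    _rxn_index: dict[str, int] = field(init=False, repr=False, compare=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.reaction_ids = list(self.reaction_ids)
        self.metabolite_ids = list(self.metabolite_ids)
        self.N = np.atleast_2d(np.asarray(self.N, dtype=float))
        self.lb = np.asarray(self.lb, dtype=float).ravel()
        self.ub = np.asarray(self.ub, dtype=float).ravel()
        m, n = self.N.shape
        if n == 0:
            raise ModelError("empty model: no reactions")
        if len(self.reaction_ids) != n:
            raise ModelError(
                f"dimension mismatch: N has {n} columns but {len(self.reaction_ids)} reaction ids"
            )
        if len(self.metabolite_ids) != m:
            raise ModelError(
                f"dimension mismatch: N has {m} rows but {len(self.metabolite_ids)} metabolite ids"
            )
        if len(set(self.reaction_ids)) != n:
            raise ModelError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise ModelError("duplicate metabolite identifiers")
        if self.lb.shape != (n,) or self.ub.shape != (n,):
            raise ModelError("lb/ub length does not match number of reactions")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            raise ModelError(f"lb > ub for reaction(s): {[self.reaction_ids[i] for i in bad]}")
        if (self.A is None) != (self.b is None):
            raise ModelError("A and b must be given together")
        if self.A is not None:
            self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
            self.b = np.asarray(self.b, dtype=float).ravel()
            if self.A.shape[1] != n:
                raise ModelError(f"constraint matrix A has {self.A.shape[1]} columns, expected {n}")
            if self.b.shape != (self.A.shape[0],):
                raise ModelError("length of b does not match number of rows of A")
        if self.objective_c is not None:
            self.objective_c = np.asarray(self.objective_c, dtype=float).ravel()
            if self.objective_c.shape != (n,):
                raise ModelError("objective coefficient vector length does not match reactions")
        self._rxn_index = {rid: i for i, rid in enumerate(self.reaction_ids)}

    # -- convenience ------------------------------------------------------

    @property
    def n_reactions(self) -> int:
        return self.N.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.N.shape[0]

    def reaction_index(self, reaction_id: str) -> int:
        try:
            return self._rxn_index[reaction_id]
        except KeyError:
            raise ScenarioError(f"unknown reaction id: {reaction_id!r}") from None

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            N=self.N.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            A=None if self.A is None else self.A.copy(),
            b=None if self.b is None else self.b.copy(),
            objective_c=None if self.objective_c is None else self.objective_c.copy(),
        )

    def with_bounds(self, lb: float = -1e6, ub: float = 1e6) -> "MetabolicModel":
        """Copy of the model with every bound replaced by ``[lb, ub]``.

        Useful to study the purely algebraic part of an inconsistency, where
        bound constraints are deliberately made irrelevant.
        """
        out = self.copy()
        out.lb = np.full(self.n_reactions, float(lb))
        out.ub = np.full(self.n_reactions, float(ub))
        return out


@dataclass
class FluxScenario:
    """A set of fixed (known/measured) reaction rates ``r_i = f_i, i in F``.

    ``variances`` optionally stores the measurement variance sigma_i^2 for
    each fixed rate (required by weighting scheme W1).
    """

    fixed: dict[str, float]
    variances: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.fixed = {str(k): float(v) for k, v in self.fixed.items()}
        if self.variances is not None:
            self.variances = {str(k): float(v) for k, v in self.variances.items()}
            for rid, var in self.variances.items():
                if rid not in self.fixed:
                    raise ScenarioError(f"variance given for non-fixed reaction {rid!r}")
                if not var > 0:
                    raise ScenarioError(f"non-positive variance for reaction {rid!r}: {var}")

    @property
    def k(self) -> int:
        return len(self.fixed)

    def validate(self, model: MetabolicModel) -> None:
        for rid in self.fixed:
            model.reaction_index(rid)
        if self.k > model.n_reactions:
            raise ScenarioError("more fixed rates than reactions")

    def values(self, ids: list[str] | None = None) -> np.ndarray:
        ids = list(self.fixed) if ids is None else ids
        return np.array([self.fixed[i] for i in ids], dtype=float)

    def copy(self) -> "FluxScenario":
        return FluxScenario(
            fixed=dict(self.fixed),
            variances=None if self.variances is None else dict(self.variances),
        )


@dataclass(frozen=True)
class WeightSpec:
    """Weighting scheme for corrections of fixed rates.

    scheme
        ``"W1"``: w_i = 1/sigma_i^2 (requires scenario variances);
        ``"W2"``: w_i = 1/|f_i| (noise assumed proportional to magnitude);
        ``"W3"``: w_i = 1 (equal weights).
    zero_flux_weight
        Large weight assigned under W1/W2 to rates fixed at zero, penalising
        corrections of fluxes believed to be off.  Must be >= 1e3.
    pin_zero_rates
        If true, rates fixed at exactly zero receive *no* correction variable
        at all (equivalent to an infinite weight).
    """

    scheme: str = "W3"
    zero_flux_weight: float = 1e6
    pin_zero_rates: bool = False

    def __post_init__(self) -> None:
        scheme = self.scheme.upper()
        if scheme not in {"W1", "W2", "W3"}:
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        object.__setattr__(self, "scheme", scheme)
        if not self.zero_flux_weight >= 1e3:
            raise ValueError("zero_flux_weight must be >= 1e3")


def as_weight_spec(weights) -> WeightSpec:
    """Coerce a WeightSpec or scheme string ('w1'/'w2'/'w3') to a WeightSpec."""
    if isinstance(weights, WeightSpec):
        return weights
    if isinstance(weights, str):
        return WeightSpec(scheme=weights)
    raise TypeError(f"cannot interpret weights of type {type(weights).__name__}")
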