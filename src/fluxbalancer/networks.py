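"""Bundled example networks and a seeded synthetic-scenario generator.

``example_network`` is a canonical 10-reaction, 6-metabolite reconstruction
of the kind of didactic network used to illustrate MFA scenario taxonomy:
four exchange reactions R1/R2 (uptake) and R3/R4 (excretion) whose rates
must balance (r1 + r2 = r3 + r4), a strictly coupled linear tail
R7 -> D -> R10 -> E -> R9 -> F -> R4 forcing r7 = r10 = r9 = r4, and two
reversible reactions (R2, R8) while all others are irreversible.

``random_scenario`` produces seeded random flux-balance scenarios with a
known ground-truth flux vector, used for property and recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._lp import solve_lp
from .exceptions import FluxBalancerError
from .model import FluxScenario, MetabolicModel

__all__ = [
    "example_network",
    "coupled_pair",
    "chain3",
    "branch_network",
    "SyntheticScenario",
    "random_scenario",
]

_INF = np.inf


def example_network() -> MetabolicModel:
    """The 10-reaction, 6-metabolite example network (reconstruction).

    Metabolites A-F; reactions::

        R1:  -> A          R6: B -> C
        R2:  -> B  (rev)   R7: C -> D
        R3: C ->           R8: A -> B (rev)
        R4: F ->           R9: E -> F
        R5: A -> C         R10: D -> E

    The stoichiometric matrix has full rank 6, so at least 10 - 6 = 4 fixed
    rates are needed for a determined scenario.  Fixing all four exchange
    rates (R1-R4) yields one degree of redundancy -- the overall exchange
    balance r1 + r2 = r3 + r4 -- in which all four rates participate.
    """
    mets = ["A", "B", "C", "D", "E", "F"]
    reactions = {
        "R1": {"A": 1},
        "R2": {"B": 1},
        "R3": {"C": -1},
        "R4": {"F": -1},
        "R5": {"A": -1, "C": 1},
        "R6": {"B": -1, "C": 1},
        "R7": {"C": -1, "D": 1},
        "R8": {"A": -1, "B": 1},
        "R9": {"E": -1, "F": 1},
        "R10": {"D": -1, "E": 1},
    }
    reversible = {"R2", "R8"}
    rxn_ids = list(reactions)
    N = np.zeros((len(mets), len(rxn_ids)))
    midx = {m: i for i, m in enumerate(mets)}
    for j, rid in enumerate(rxn_ids):
        for mid, coef in reactions[rid].items():
            N[midx[mid], j] = coef
    lb = np.array([-_INF if rid in reversible else 0.0 for rid in rxn_ids])
    ub = np.full(len(rxn_ids), _INF)
    return MetabolicModel(reaction_ids=rxn_ids, metabolite_ids=mets, N=N, lb=lb, ub=ub)


def coupled_pair() -> MetabolicModel:
    """Minimal strictly coupled irreversible pair: R4 -> D -> R10.

    The single balance around D forces r4 = r10, so any scenario fixing the
    two rates at different values is redundant and inconsistent.
    """
    return MetabolicModel(
        reaction_ids=["R4", "R10"],
        metabolite_ids=["D"],
        N=np.array([[1.0, -1.0]]),
        lb=np.zeros(2),
        ub=np.full(2, _INF),
    )


def chain3(ub_r1: float | None = None) -> MetabolicModel:
    """Irreversible 3-reaction chain R1 -> A -> R2 -> B -> R3."""
    ub = np.full(3, _INF)
    if ub_r1 is not None:
        ub[0] = ub_r1
    return MetabolicModel(
        reaction_ids=["R1", "R2", "R3"],
        metabolite_ids=["A", "B"],
        N=np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]]),
        lb=np.zeros(3),
        ub=ub,
    )


def branch_network() -> MetabolicModel:
    """One influx R1 into metabolite A, two irreversible effluxes R2 and R3."""
    return MetabolicModel(
        reaction_ids=["R1", "R2", "R3"],
        metabolite_ids=["A"],
        N=np.array([[1.0, -1.0, -1.0]]),
        lb=np.zeros(3),
        ub=np.full(3, _INF),
    )


# ---------------------------------------------------------------------------
# synthetic scenarios


@dataclass
class SyntheticScenario:
    """A model plus a ground-truth steady-state flux vector and a scenario
    fixing a noisy subset of it.

    ``true_fluxes`` satisfies N r = 0 and all bounds (to solver precision,
    <= 1e-9); with ``sigma = 0`` the scenario is exactly consistent.
    """

    model: MetabolicModel
    true_fluxes: np.ndarray
    scenario: FluxScenario
    sigma: float
    seed: int

    def true_flux(self, reaction_id: str) -> float:
        return float(self.true_fluxes[self.model.reaction_index(reaction_id)])


def random_scenario(
    seed: int,
    m: int | None = None,
    n: int | None = None,
    k: int | None = None,
    sigma: float = 0.1,
    reversible_fraction: float = 0.3,
    *,
    max_attempts: int = 80,
) -> SyntheticScenario:
    """Seeded random model + scenario with known ground truth.

    The stoichiometry is sparse with integer coefficients in {-2,-1,1,2};
    a ground-truth flux vector is sampled by averaging vertices of the flux
    polytope obtained from LPs with random objectives (an interior-leaning
    point), the fixed subset is drawn at random, and iid Gaussian noise of
    standard deviation ~``sigma`` (per-rate sigmas drawn in
    [0.5, 1.5] * sigma, recorded as scenario variances) is added to the
    fixed values.  Identical seeds give identical scenarios.
    """
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        m_ = int(m) if m is not None else int(rng.integers(3, 9))
        lo_n = max(6, m_ + 2)
        n_ = int(n) if n is not None else int(rng.integers(lo_n, 17))
        if not n_ > m_:
            raise ValueError("need n > m")
        model = _random_model(rng, m_, n_, reversible_fraction)
        if model is None:
            continue
        r_star = _sample_interior(rng, model)
        if r_star is None or np.abs(r_star).max() < 0.5:
            continue
        k_ = int(k) if k is not None else int(rng.integers(2, n_))
        k_ = min(k_, n_)
        fixed_idx = rng.choice(n_, size=k_, replace=False)
        fixed: dict[str, float] = {}
        variances: dict[str, float] = {}
        for i in sorted(int(v) for v in fixed_idx):
            rid = model.reaction_ids[i]
            if sigma > 0:
                s_i = sigma * rng.uniform(0.5, 1.5)
                fixed[rid] = float(r_star[i] + rng.normal(0.0, s_i))
                variances[rid] = s_i**2
            else:
                fixed[rid] = float(r_star[i])
        scenario = FluxScenario(fixed=fixed, variances=variances or None)
        return SyntheticScenario(
            model=model, true_fluxes=r_star, scenario=scenario, sigma=sigma, seed=seed
        )
    raise FluxBalancerError(
        f"could not generate a non-degenerate scenario for seed {seed} "
        f"within {max_attempts} attempts"
    )


def redundant_scenarios(
    count: int,
    start_seed: int = 0,
    sigma: float = 0.1,
    *,
    require_inconsistent: bool = False,
    m: int | None = 5,
    n: int | None = 10,
    k: int | None = 8,
    max_seeds: int | None = None,
):
    """Yield ``count`` synthetic scenarios with at least one degree of
    redundancy (optionally requiring steady-state inconsistency), scanning
    seeds from ``start_seed``.  Deterministic for fixed arguments."""
    from .mfa import diagnose  # deferred to keep module imports one-way

    found = 0
    seed = start_seed
    limit = max_seeds if max_seeds is not None else 200 * max(count, 1)
    while found < count and seed < start_seed + limit:
        syn = random_scenario(seed, m=m, n=n, k=k, sigma=sigma)
        diag = diagnose(syn.model, syn.scenario)
        seed += 1
        if diag.degR < 1:
            continue
        if require_inconsistent and diag.consistency != "inconsistent":
            continue
        yield syn, diag
        found += 1
    if found < count:
        raise FluxBalancerError(
            f"only {found}/{count} redundant scenarios found in {limit} seeds"
        )


def _random_model(rng, m, n, reversible_fraction):
    mets = [f"M{i}" for i in range(m)]
    N = np.zeros((m, n))
    n_exchange = max(2, int(round(0.3 * n)))
    for j in range(n):
        if j < n_exchange:
            i = j % m if j < m else int(rng.integers(m))
            N[i, j] = 1.0 if j % 2 == 0 else -1.0  # alternate uptake/excretion
        else:
            n_sub = 2 if rng.random() < 0.8 else 3
            mets_j = rng.choice(m, size=min(n_sub, m), replace=False)
            coefs = rng.choice([-2.0, -1.0, 1.0, 2.0], size=len(mets_j))
            if np.all(coefs > 0) or np.all(coefs < 0):  # force consume+produce
                coefs[0] = -coefs[0]
            N[mets_j, j] = coefs
    # every metabolite must appear in some reaction
    if np.any(np.all(N == 0.0, axis=1)):
        return None
    rev = rng.random(n) < reversible_fraction
    lb = np.where(rev, -10.0, 0.0)
    ub = np.full(n, 10.0)
    return MetabolicModel(
        reaction_ids=[f"R{j + 1}" for j in range(n)],
        metabolite_ids=mets,
        N=N,
        lb=lb,
        ub=ub,
    )


def _sample_interior(rng, model, n_vertices: int = 4):
    bounds = list(zip(model.lb, model.ub))
    A_eq = model.N
    b_eq = np.zeros(model.n_metabolites)
    vertices = []
    for _ in range(n_vertices):
        c = rng.normal(size=model.n_reactions)
        res = solve_lp(-c, A_eq=A_eq, b_eq=b_eq, bounds=bounds)
        if res.status != "optimal":
            return None
        vertices.append(res.x)
    r = np.mean(vertices, axis=0)
    # re-project onto the nullspace of N (vertex solutions carry LP tolerance)
    r = r - np.linalg.pinv(model.N) @ (model.N @ r)
    if np.any(r < model.lb - 1e-7) or np.any(r > model.ub + 1e-7):
        return None
    return r
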