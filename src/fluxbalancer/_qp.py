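"""Dense convex quadratic programming.

Solves

    minimize    0.5 x' P x + q' x
    subject to  E x  = e
                G x <= h

with P symmetric positive semidefinite, by a Mehrotra predictor-corrector
primal-dual interior-point method followed by an active-set "polish" step
that re-solves the KKT system of the identified active constraints to near
machine precision.  Intended for the small, dense correction problems that
arise when balancing flux scenarios (tens to a few hundred variables); it is
not a general-purpose large-scale solver.

The semidefinite case (flux variables carry no quadratic cost) is handled by
a tiny static regularization of the (1,1) block; the polish step removes the
regularization bias from the returned solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

__all__ = ["QPResult", "solve_qp"]

_REG = 1e-10  # static KKT regularization


@dataclass
class QPResult:
    x: np.ndarray
    objective: float
    status: str  # "optimal" | "max_iter"
    iterations: int
    polished: bool


def _objective(P, q, x) -> float:
    return 0.5 * float(x @ P @ x) + float(q @ x)


def _solve_kkt_ls(P, q, Aeq, beq):
    """Min-norm solution of the equality-constrained QP KKT system."""
    n = len(q)
    p = 0 if Aeq is None else Aeq.shape[0]
    K = np.zeros((n + p, n + p))
    K[:n, :n] = P
    rhs = np.concatenate([-q, np.zeros(0) if beq is None else beq])
    if p:
        K[:n, n:] = Aeq.T
        K[n:, :n] = Aeq
    sol, *_ = scipy.linalg.lstsq(K, rhs, lapack_driver="gelsd")
    return sol[:n]


def solve_qp(
    P: np.ndarray,
    q: np.ndarray,
    E: np.ndarray | None = None,
    e: np.ndarray | None = None,
    G: np.ndarray | None = None,
    h: np.ndarray | None = None,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> QPResult:
    """Solve the convex QP; assumes the problem is feasible and bounded.

    Callers are expected to have established feasibility beforehand (e.g. by
    an LP phase-1 solve); behaviour on infeasible input is a "max_iter"
    status, not a certificate.
    """
    P = np.atleast_2d(np.asarray(P, dtype=float))
    q = np.asarray(q, dtype=float).ravel()
    n = q.size
    if E is not None:
        E = np.atleast_2d(np.asarray(E, dtype=float))
        e = np.asarray(e, dtype=float).ravel()
        if E.shape[0] == 0:
            E, e = None, None
    if G is not None:
        G = np.atleast_2d(np.asarray(G, dtype=float))
        h = np.asarray(h, dtype=float).ravel()
        if G.shape[0] == 0:
            G, h = None, None

    if G is None:  # pure equality QP: single KKT solve
        x = _solve_kkt_ls(P, q, E, e)
        return QPResult(x, _objective(P, q, x), "optimal", 0, True)

    mI = G.shape[0]
    p = 0 if E is None else E.shape[0]

    # starting point
    if E is not None:
        x, *_ = scipy.linalg.lstsq(E, e, lapack_driver="gelsd")
    else:
        x = np.zeros(n)
    s = np.maximum(1.0, np.abs(h - G @ x))
    z = np.ones(mI)
    y = np.zeros(p)

    scale = 1.0 + max(
        np.abs(q).max(initial=0.0),
        np.abs(h).max(initial=0.0),
        0.0 if e is None else np.abs(e).max(initial=0.0),
    )
    status = "max_iter"
    it = 0
    for it in range(1, max_iter + 1):
        rd = P @ x + q + G.T @ z + (E.T @ y if E is not None else 0.0)
        rp = (E @ x - e) if E is not None else np.zeros(0)
        rg = G @ x + s - h
        mu = float(s @ z) / mI
        if (
            np.abs(rd).max(initial=0.0) <= tol * scale
            and np.abs(rp).max(initial=0.0) <= tol * scale
            and np.abs(rg).max(initial=0.0) <= tol * scale
            and mu <= tol * scale
        ):
            status = "optimal"
            break

        dim = n + p + mI
        K = np.zeros((dim, dim))
        K[:n, :n] = P + _REG * np.eye(n)
        if p:
            K[:n, n : n + p] = E.T
            K[n : n + p, :n] = E
            K[n : n + p, n : n + p] = -_REG * np.eye(p)
        K[:n, n + p :] = G.T
        K[n + p :, :n] = G
        K[n + p :, n + p :] = -np.diag(s / z)
        try:
            lu = scipy.linalg.lu_factor(K)
        except scipy.linalg.LinAlgError:
            break

        def newton(rc):
            rhs = np.concatenate([-rd, -rp, -rg + rc / z])
            sol = scipy.linalg.lu_solve(lu, rhs)
            dx = sol[:n]
            dy = sol[n : n + p]
            dz = sol[n + p :]
            ds = -(rc + s * dz) / z
            return dx, dy, dz, ds

        # affine (predictor) direction
        dxa, dya, dza, dsa = newton(s * z)
        ap = _max_step(s, dsa)
        ad = _max_step(z, dza)
        mu_aff = float((s + ap * dsa) @ (z + ad * dza)) / mI
        sigma = (max(mu_aff, 0.0) / mu) ** 3 if mu > 0 else 0.0

        # corrector
        dx, dy, dz, ds = newton(s * z - sigma * mu + dsa * dza)
        ap = 0.995 * _max_step(s, ds)
        ad = 0.995 * _max_step(z, dz)
        x = x + ap * dx
        s = np.maximum(s + ap * ds, 1e-300)
        y = y + ad * dy
        z = np.maximum(z + ad * dz, 1e-300)

    x_best = x
    polished = False
    # active-set polish: re-solve KKT with the active inequalities as equalities
    active = np.nonzero(z * np.maximum(s, 1e-300) ** -1 > 1.0)[0]
    feas_tol = 1e-8 * scale
    for _ in range(2):
        rows = [E] if E is not None else []
        rhs = [e] if e is not None else []
        if active.size:
            rows.append(G[active])
            rhs.append(h[active])
        Aeq = np.vstack(rows) if rows else None
        beq = np.concatenate(rhs) if rhs else None
        xp = _solve_kkt_ls(P, q, Aeq, beq)
        viol = G @ xp - h
        if np.all(viol <= feas_tol) and (
            E is None or np.abs(E @ xp - e).max(initial=0.0) <= feas_tol
        ):
            if _objective(P, q, xp) <= _objective(P, q, x_best) + 1e-9 * scale:
                x_best = xp
                polished = True
            break
        # one repair attempt: add the violated rows to the active set
        active = np.union1d(active, np.nonzero(viol > feas_tol)[0])

    return QPResult(x_best, _objective(P, q, x_best), status, it, polished)


def _max_step(v: np.ndarray, dv: np.ndarray) -> float:
    neg = dv < 0
    if not np.any(neg):
        return 1.0
    return min(1.0, float(np.min(-v[neg] / dv[neg])))
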