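"""Optimal contribution selection as a scalarized convex quadratic program.

For candidates with breeding values ``Y`` and a positive-definite
relationship matrix ``M``, the contribution vector ``c`` solves

    minimize    alpha * c'Mc - (1 - alpha) * c'Y
    subject to  sum(c) = 1,  0 <= c_i <= upper_bound
                (optionally d'c = 0.5 for a dioecious design vector d)

where ``alpha`` in [0, 1] weights coancestry against genetic gain. Sweeping
``alpha`` traces the Pareto curve of (coancestry, gain) optima; the cap
``upper_bound = 0.5`` prevents any single parent from supplying more than
half the gametes (no selfing).

The solver is a primal active-set method on the box constraints with exact
KKT solves on the free set — deterministic, no random initialization — and
the returned solution carries its own KKT residual so optimality is
checkable. A SLSQP fallback guards the (never observed) event of the
active-set iteration failing to converge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.optimize

__all__ = ["OCSProblem", "OCSSolution", "solve_ocs", "pareto_sweep"]

_ALPHA_FLOOR = 1e-9  # quadratic regularization for the alpha = 0 LP limit


@dataclass
class OCSProblem:
    """One scalarized OCS instance."""

    M: np.ndarray
    Y: np.ndarray
    alpha: float
    upper_bound: float = 0.5
    sex_design: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.Y.shape[0]
        if self.M.shape != (n, n):
            raise ValueError("M must be N x N matching Y")
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 < self.upper_bound <= 1.0):
            raise ValueError("upper_bound must lie in (0, 1]")
        if n * self.upper_bound < 1.0 - 1e-12:
            raise ValueError(
                f"infeasible: {n} candidates with cap {self.upper_bound} "
                "cannot reach total contribution 1"
            )
        if self.sex_design is not None:
            self.sex_design = np.asarray(self.sex_design, dtype=float)
            if self.sex_design.shape != (n,):
                raise ValueError("sex_design must be length N")
            if not np.isin(self.sex_design, (0.0, 1.0)).all():
                raise ValueError("sex_design must be 0/1")
            for group, want in ((self.sex_design, 0.5), (1 - self.sex_design, 0.5)):
                if group.sum() * self.upper_bound < want - 1e-12:
                    raise ValueError("infeasible sex constraint: group too small")

    @property
    def n(self) -> int:
        return self.Y.shape[0]


@dataclass
class OCSSolution:
    """Optimal contributions plus the diagnostics needed to audit them."""

    c: np.ndarray
    objective: float
    cY: float
    cMc: float
    kkt_residual: float
    status: str
    alpha: float
    n_iterations: int = 0


def _equality_system(problem: OCSProblem) -> tuple[np.ndarray, np.ndarray]:
    n = problem.n
    rows = [np.ones(n)]
    rhs = [1.0]
    if problem.sex_design is not None:
        rows.append(problem.sex_design)
        rhs.append(0.5)
    return np.vstack(rows), np.asarray(rhs)


def _feasible_start(problem: OCSProblem) -> np.ndarray:
    """Equal-share start with the cap enforced by water-filling."""
    n, ub = problem.n, problem.upper_bound

    def fill(idx: np.ndarray, total: float) -> np.ndarray:
        # equal shares, clipped at ub, remainder spread over unclipped entries
        c = np.zeros(n)
        free = list(idx)
        remaining = total
        while free:
            share = remaining / len(free)
            if share <= ub + 1e-15:
                for i in free:
                    c[i] = share
                break
            c[free[0]] = ub
            remaining -= ub
            free = free[1:]
        return c

    if problem.sex_design is None:
        return fill(np.arange(n), 1.0)
    females = np.flatnonzero(problem.sex_design == 1)
    males = np.flatnonzero(problem.sex_design == 0)
    return fill(females, 0.5) + fill(males, 0.5)


def _kkt_residual(
    c: np.ndarray, H: np.ndarray, q: np.ndarray, problem: OCSProblem
) -> float:
    """Max violation of stationarity, complementarity and feasibility.

    Equality multipliers are not unique when bounds are degenerate with the
    simplex constraint, so the stationarity violation is minimized over the
    multipliers with a small auxiliary LP before being reported.
    """
    n, ub = problem.n, problem.upper_bound
    A, b = _equality_system(problem)
    n_eq = A.shape[0]
    g = H @ c + q
    scale = max(1.0, float(np.max(np.abs(g))))
    tol = 1e-7
    lower = c <= tol
    upper = c >= ub - tol
    free = ~(lower | upper)
    # variables (mu_1..mu_k, s): minimize s over the signed stationarity cone
    rows, rhs = [], []
    for i in range(n):
        a_i = A[:, i]
        if free[i]:  # -s <= g_i - a_i'mu <= s
            rows.append(np.concatenate([a_i, [-1.0]])); rhs.append(g[i])
            rows.append(np.concatenate([-a_i, [-1.0]])); rhs.append(-g[i])
        elif lower[i]:  # need g_i - a_i'mu >= -s
            rows.append(np.concatenate([a_i, [-1.0]])); rhs.append(g[i])
        else:  # upper: need g_i - a_i'mu <= s
            rows.append(np.concatenate([-a_i, [-1.0]])); rhs.append(-g[i])
    obj = np.zeros(n_eq + 1)
    obj[-1] = 1.0
    lp = scipy.optimize.linprog(
        obj,
        A_ub=np.array(rows),
        b_ub=np.array(rhs),
        bounds=[(None, None)] * n_eq + [(0, None)],
        method="highs",
    )
    res = float(lp.x[-1]) if lp.success else float("inf")
    res = max(res, float(np.max(np.abs(A @ c - b))) * scale)
    res = max(res, float(np.max(np.maximum(0.0, -c), initial=0.0)) * scale)
    res = max(res, float(np.max(np.maximum(0.0, c - ub), initial=0.0)) * scale)
    return res / scale


def _active_set_qp(
    H: np.ndarray, q: np.ndarray, problem: OCSProblem
) -> tuple[np.ndarray, int, bool]:
    """Primal active-set method for the box+equality QP; H must be PD."""
    n, ub = problem.n, problem.upper_bound
    A, b = _equality_system(problem)
    n_eq = A.shape[0]
    c = _feasible_start(problem)
    at_lower = np.zeros(n, dtype=bool)
    at_upper = np.zeros(n, dtype=bool)
    at_lower[c <= 1e-14] = True
    at_upper[c >= ub - 1e-14] = True
    max_iter = 50 * (n + 5)

    for it in range(1, max_iter + 1):
        free = np.flatnonzero(~(at_lower | at_upper))
        bound = np.flatnonzero(at_lower | at_upper)
        target = c.copy()
        if free.size >= n_eq:
            Af = A[:, free]
            Hf = H[np.ix_(free, free)]
            rhs_eq = b - A[:, bound] @ c[bound] if bound.size else b.copy()
            qf = q[free] + (H[np.ix_(free, bound)] @ c[bound] if bound.size else 0.0)
            kkt = np.block(
                [[Hf, Af.T], [Af, np.zeros((n_eq, n_eq))]]
            )
            rhs = np.concatenate([-qf, rhs_eq])
            try:
                sol = scipy.linalg.solve(kkt, rhs, assume_a="sym")
                target[free] = sol[:free.size]
            except scipy.linalg.LinAlgError:
                pass
        p = target - c
        if np.max(np.abs(p), initial=0.0) <= 1e-13 * max(1.0, np.max(np.abs(c))):
            # stationary on the working set: check bound multipliers
            g = H @ c + q
            if free.size:
                mu, *_ = np.linalg.lstsq(A[:, free].T, g[free], rcond=None)
            else:
                mu, *_ = np.linalg.lstsq(A.T, g, rcond=None)
            lam = g - A.T @ mu
            scale = max(1.0, float(np.max(np.abs(g))))
            worst, worst_i, worst_kind = -1e-9 * scale, -1, None
            for i in np.flatnonzero(at_lower):
                if lam[i] < worst:
                    worst, worst_i, worst_kind = lam[i], i, "lower"
            for i in np.flatnonzero(at_upper):
                if -lam[i] < worst:
                    worst, worst_i, worst_kind = -lam[i], i, "upper"
            if worst_i < 0:
                return c, it, True
            if worst_kind == "lower":
                at_lower[worst_i] = False
            else:
                at_upper[worst_i] = False
            continue
        # step toward the EQP target until a bound blocks
        t = 1.0
        block_i, block_kind = -1, None
        for i in free:
            if p[i] < -1e-15:
                tb = (0.0 - c[i]) / p[i]
                if tb < t - 1e-15:
                    t, block_i, block_kind = tb, i, "lower"
            elif p[i] > 1e-15:
                tb = (ub - c[i]) / p[i]
                if tb < t - 1e-15:
                    t, block_i, block_kind = tb, i, "upper"
        t = max(t, 0.0)
        c = c + t * p
        np.clip(c, 0.0, ub, out=c)
        if block_i >= 0:
            if block_kind == "lower":
                c[block_i] = 0.0
                at_lower[block_i] = True
            else:
                c[block_i] = ub
                at_upper[block_i] = True
    return c, max_iter, False


def _slsqp_fallback(H, q, problem: OCSProblem) -> np.ndarray:
    A, b = _equality_system(problem)
    res = scipy.optimize.minimize(
        lambda c: 0.5 * c @ H @ c + q @ c,
        _feasible_start(problem),
        jac=lambda c: H @ c + q,
        bounds=[(0.0, problem.upper_bound)] * problem.n,
        constraints=[
            {"type": "eq", "fun": (lambda c, r=r: A[r] @ c - b[r])}
            for r in range(A.shape[0])
        ],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-14},
    )
    return res.x


def solve_ocs(problem: OCSProblem) -> OCSSolution:
    """Solve one scalarized OCS instance to KKT tolerance 1e-6.

    ``alpha = 0`` (pure gain maximization, an LP with possibly non-unique
    optima) is regularized with a 1e-9 quadratic weight so the solution stays
    deterministic; remaining ties resolve by candidate index through the
    deterministic linear algebra.
    """
    alpha = problem.alpha
    alpha_eff = max(alpha, _ALPHA_FLOOR)
    gain_w = 1.0 - alpha
    H = alpha_eff * (problem.M + problem.M.T)  # Hessian of alpha*c'Mc
    q = -gain_w * problem.Y
    c, n_iter, converged = _active_set_qp(H, q, problem)
    status = "optimal"
    res = _kkt_residual(c, H, q, problem)
    if not converged or res > 1e-6:
        c2 = _slsqp_fallback(H, q, problem)
        res2 = _kkt_residual(c2, H, q, problem)
        if res2 < res:
            c, res = c2, res2
        status = "optimal" if res <= 1e-6 else "max_iterations"
    # snap numerical dust so downstream discretization sees clean zeros
    c = np.where(c < 1e-12, 0.0, c)
    c = c / c.sum()
    cY = float(c @ problem.Y)
    cMc = float(c @ problem.M @ c)
    return OCSSolution(
        c=c,
        objective=alpha * cMc - (1.0 - alpha) * cY,
        cY=cY,
        cMc=cMc,
        kkt_residual=res,
        status=status,
        alpha=alpha,
        n_iterations=n_iter,
    )


def pareto_sweep(
    M: np.ndarray,
    Y: np.ndarray,
    alpha_grid,
    upper_bound: float = 0.5,
    sex_design: np.ndarray | None = None,
) -> list[OCSSolution]:
    """Solve the OCS program for each alpha, tracing the Pareto curve.

    Along the sweep both ``c'Y`` (gain) and ``c'Mc`` (coancestry) are
    nonincreasing in alpha; failures on individual grid points are recorded
    in the solution status and the sweep continues.
    """
    solutions: list[OCSSolution] = []
    for alpha in alpha_grid:
        try:
            sol = solve_ocs(
                OCSProblem(
                    M=M, Y=Y, alpha=float(alpha),
                    upper_bound=upper_bound, sex_design=sex_design,
                )
            )
        except ValueError as exc:
            sol = OCSSolution(
                c=np.full(np.asarray(Y).shape[0], np.nan),
                objective=np.nan, cY=np.nan, cMc=np.nan,
                kkt_residual=np.inf, status=f"error: {exc}", alpha=float(alpha),
            )
        solutions.append(sol)
    return solutions
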