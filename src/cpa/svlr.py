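"""ε-insensitive linear support-vector regression (SVLR) solved in-package.

The model predicts one clinotype from all others with a linear function
``ŷ = wᵀx + b``.  Training solves the convex quadratic program

    minimize   ½‖w‖² + C Σ_n ξ_n
    subject to |wᵀx_n + b − y_n| ≤ ε + ξ_n,   ξ_n ≥ 0,

i.e. residuals inside the ε band are free and excess error is penalized
linearly with weight C.  (A single slack per sample is equivalent to the
usual ξ/ξ* pair because at most one side of the band can be violated.)

The solver works on the dual: with β_n ∈ [−C, C] and Σβ_n = 0,

    minimize  f(β) = ½ βᵀKβ − yᵀβ + ε‖β‖₁,      K = XXᵀ,

by sequential minimal optimization (SMO): repeatedly pick the
maximal-violating coordinate pair, with a second-order working-set
refinement, and solve the one-dimensional piecewise-quadratic subproblem
exactly.  The intercept is recovered afterwards by exact minimization of
the one-dimensional piecewise-linear primal in b; on a flat optimum the
midpoint is taken (so a constant target y = c yields w = 0, b = c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit


class SolverError(RuntimeError):
    """The SMO loop failed to reach the requested KKT tolerance."""


@njit(cache=True)
def _smo_kernel(K, y, C, eps, tol, max_iter):  # pragma: no cover - jitted
    """SMO inner loop on the dual; returns (beta, n_iter, converged).

    Working-set selection: i minimizes the right derivative among
    coordinates free to increase; j maximizes the second-order gain
    (violation² / curvature) among coordinates free to decrease.  The
    1-D subproblem is solved exactly over its candidate breakpoints.
    """
    n = y.shape[0]
    beta = np.zeros(n)
    g = -y.copy()  # gradient of the smooth part: Kβ − y
    diag = np.empty(n)
    for a in range(n):
        diag[a] = K[a, a]
    it = 0
    converged = False
    cand = np.empty(8)
    while it < max_iter:
        it += 1
        best_i = -1
        bestR = 1e300
        for a in range(n):
            if beta[a] < C - 1e-15:
                s = 1.0 if beta[a] >= 0 else -1.0
                r = g[a] + eps * s
                if r < bestR:
                    bestR = r
                    best_i = a
        if best_i < 0:
            converged = True
            break
        best_j = -1
        best_gain = 0.0
        maxviol = -1e300
        for a in range(n):
            if beta[a] > -C + 1e-15:
                s = 1.0 if beta[a] > 0 else -1.0
                viol = g[a] + eps * s - bestR
                if viol > maxviol:
                    maxviol = viol
                if viol > 0.0:
                    eta = diag[best_i] + diag[a] - 2.0 * K[best_i, a]
                    if eta < 1e-12:
                        eta = 1e-12
                    gain = viol * viol / eta
                    if gain > best_gain:
                        best_gain = gain
                        best_j = a
        if maxviol <= tol or best_j < 0:
            converged = True
            break
        i = best_i
        j = best_j
        lo = max(-C - beta[i], beta[j] - C)
        hi = min(C - beta[i], beta[j] + C)
        eta_ij = diag[i] + diag[j] - 2.0 * K[i, j]
        if eta_ij < 0.0:
            eta_ij = 0.0
        glin = g[i] - g[j]
        cand[0] = lo
        cand[1] = hi
        cand[2] = -beta[i]
        cand[3] = beta[j]
        nc = 4
        if eta_ij > 1e-12:
            for s1 in (-1.0, 1.0):
                for s2 in (-1.0, 1.0):
                    cand[nc] = -(glin + eps * (s1 - s2)) / eta_ij
                    nc += 1
        best_t = 0.0
        best_phi = 1e300
        for c in range(nc):
            t = cand[c]
            if t < lo:
                t = lo
            if t > hi:
                t = hi
            phi = (
                0.5 * eta_ij * t * t
                + glin * t
                + eps * (abs(beta[i] + t) + abs(beta[j] - t))
            )
            if phi < best_phi:
                best_phi = phi
                best_t = t
        if best_t == 0.0:
            converged = True
            break
        beta[i] += best_t
        beta[j] -= best_t
        for a in range(n):
            g[a] += best_t * (K[i, a] - K[j, a])
    return beta, it, converged


@dataclass(frozen=True)
class SVLRConfig:
    """Hyper-parameters of the resampling-averaged imputer.

    C and ε trade off flatness of the regression function against
    tolerated deviation; defaults follow the values selected for the
    framework (C = 1, ε = 0.001, 50 resampling repetitions).
    """

    C: float = 1.0
    epsilon: float = 0.001
    n_repetitions: int = 50
    seed: int = 0
    #: KKT tolerance for the resampled fits; coefficients are stable well
    #: before full dual convergence, so this trades precision for speed.
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclass
class SVLRSolution:
    w: np.ndarray
    b: float
    xi: np.ndarray  # slack per training sample
    objective: float  # primal objective value
    beta: np.ndarray  # dual variables
    n_iter: int
    converged: bool

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.w + self.b


def _solve_b(residuals: np.ndarray, epsilon: float) -> float:
    """Exact 1-D minimizer of C·Σ max(0, |r_n − b| − ε) over b.

    The objective is convex piecewise linear with breakpoints r_n ± ε, so
    the minimum is attained at a breakpoint or on a flat segment between
    two; the midpoint of the minimizing breakpoints is returned.
    """
    candidates = np.concatenate([residuals - epsilon, residuals + epsilon])
    cost = np.maximum(0.0, np.abs(residuals[None, :] - candidates[:, None]) - epsilon).sum(axis=1)
    best = cost.min()
    flat = candidates[cost <= best + 1e-12]
    return float((flat.min() + flat.max()) / 2.0)


def fit_svlr(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    epsilon: float = 0.001,
    tol: float = 1e-8,
    max_iter: int | None = None,
) -> SVLRSolution:
    """Solve the SVLR quadratic program by SMO on the dual.

    Parameters
    ----------
    X : (n, d) predictor matrix with no missing entries.
    y : (n,) target values.
    tol : KKT-violation stopping tolerance on the dual.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X must be (n, d) aligned with y")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two training rows")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite (fill predictor gaps first)")

    K = X @ X.T
    if max_iter is None:
        max_iter = max(200000, 10000 * n)
    beta, it, converged = _smo_kernel(
        np.ascontiguousarray(K), y, float(C), float(epsilon), float(tol), int(max_iter)
    )

    w = X.T @ beta
    residuals = y - X @ w
    b = _solve_b(residuals, epsilon)
    xi = np.maximum(0.0, np.abs(residuals - b) - epsilon)
    objective = 0.5 * float(w @ w) + C * float(xi.sum())
    if not converged and it >= max_iter:
        raise SolverError(
            f"SMO did not reach tol={tol} in {max_iter} iterations "
            f"(n={n}, d={X.shape[1]}, C={C}, eps={epsilon})"
        )
    return SVLRSolution(
        w=w, b=b, xi=xi, objective=objective, beta=beta, n_iter=it, converged=converged
    )
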