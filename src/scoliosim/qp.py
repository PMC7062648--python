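"""Strictly convex box-constrained equality QP solver.

Solves  min 1/2 sum h_i x_i^2  s.t.  A x = b,  lb <= x <= ub  (h_i > 0),
the form taken by the muscle-redundancy problem: a diagonal, strictly convex
objective with hard moment-equilibrium constraints and activation bounds.

Strategy: maximize the Lagrangian dual over the constraint multipliers.  The
box-projected primal x(lam) = clip(A^T lam / h, lb, ub) makes the dual
concave, piecewise quadratic and differentiable, so a semismooth Newton
iteration with an Armijo line search converges in a handful of steps; the
active bound set is then polished with exact KKT solves on the free
variables, bringing the equality residual to machine precision.  A slower
sequential-quadratic-programming fallback guards rare hard instances.  The
procedure is fully deterministic: no random initialization, identical
inputs give identical outputs.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear, minimize


class InfeasibleError(RuntimeError):
    """No bounded solution satisfies the equality constraints."""

    def __init__(self, message: str, worst_row: int | None = None, residual: float = np.nan):
        super().__init__(message)
        self.worst_row = worst_row
        self.residual = residual


def _dual_newton(
    h: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-11,
) -> np.ndarray:
    """Semismooth Newton ascent on the dual; returns the multipliers."""
    m, n = A.shape
    lam = np.zeros(m)

    def primal(l: np.ndarray) -> np.ndarray:
        return np.clip((A.T @ l) / h, lb, ub)

    def dual_val(l: np.ndarray) -> float:
        x = primal(l)
        return 0.5 * np.sum(h * x * x) - l @ (A @ x - b)

    g_scale = max(1.0, float(np.linalg.norm(b)))
    for _ in range(max_iter):
        x = primal(lam)
        grad = b - A @ x  # ascent direction component
        if np.max(np.abs(grad)) <= tol * g_scale:
            break
        free = ((A.T @ lam) / h > lb) & ((A.T @ lam) / h < ub)
        Af = A[:, free]
        J = (Af / h[free]) @ Af.T
        J[np.diag_indices_from(J)] += 1e-12
        try:
            step = np.linalg.solve(J, grad)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(J, grad, rcond=None)
        # Armijo backtracking on the (concave) dual value
        f0 = dual_val(lam)
        slope = grad @ step
        if slope <= 0:  # numerical stall: fall back to gradient direction
            step = grad
            slope = grad @ grad
        t = 1.0
        for _ls in range(60):
            if dual_val(lam + t * step) >= f0 + 1e-4 * t * slope:
                break
            t *= 0.5
        lam = lam + t * step
    return lam


def _polish(
    h: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    lam: np.ndarray,
    kkt_tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray]:
    """Active-set refinement with exact KKT solves on the free variables."""
    x = np.clip((A.T @ lam) / h, lb, ub)
    grad_dual = A.T @ lam
    for _ in range(80):
        at_lo = (x <= lb + 1e-9) & (grad_dual / h <= lb + 1e-9)
        at_hi = (x >= ub - 1e-9) & (grad_dual / h >= ub - 1e-9)
        free = ~(at_lo | at_hi)
        x_fix = np.where(at_lo, lb, np.where(at_hi, ub, 0.0))
        rhs = b - A[:, ~free] @ x_fix[~free]
        Af = A[:, free]
        K = (Af / h[free]) @ Af.T
        try:
            lam_new = np.linalg.solve(K + 1e-14 * np.eye(len(K)), rhs)
        except np.linalg.LinAlgError:
            lam_new, *_ = np.linalg.lstsq(K, rhs, rcond=None)
        x_new = np.where(free, (A.T @ lam_new) / h, x_fix)
        violation = float(np.max(np.maximum(lb - x_new, x_new - ub), initial=0.0))
        x = np.clip(x_new, lb, ub)
        grad_dual = A.T @ lam_new
        mu = h * x - grad_dual
        release = (at_lo & (mu < -kkt_tol)) | (at_hi & (mu > kkt_tol))
        lam = lam_new
        if violation <= 1e-12 and not release.any():
            break
    return x, lam


def _sqp_fallback(
    h: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
) -> np.ndarray | None:
    """Feasible-seeded SQP solve; returns x or None when it fails."""
    seed = lsq_linear(A, b, bounds=(lb, ub), tol=1e-12, max_iter=500)
    x0 = np.clip(seed.x, lb, ub)
    res = minimize(
        lambda x: (float(np.sum(h * x * x)) / 2.0, h * x),
        x0,
        jac=True,
        method="SLSQP",
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda x: A @ x - b, "jac": lambda x: A}],
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x if res.success or res.status == 8 else None


def solve_box_eq_qp(
    h: np.ndarray,
    A: np.ndarray,
    b: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    residual_tol: float = 1e-8,
    kkt_tol: float = 1e-9,
    row_labels: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, lam) minimizing 1/2 x^T diag(h) x on {Ax=b, lb<=x<=ub}.

    Raises :class:`InfeasibleError` (naming the worst constraint row) when no
    feasible point exists within the bounds.
    """
    h = np.asarray(h, dtype=float)
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    lb = np.asarray(lb, dtype=float)
    ub = np.asarray(ub, dtype=float)
    if np.any(h <= 0):
        raise ValueError("h must be strictly positive")
    if np.any(lb > ub):
        raise ValueError("lb must not exceed ub")

    # Row scaling improves dual conditioning (rows mix N*m and N units).
    row_norm = np.linalg.norm(A, axis=1)
    row_norm[row_norm < 1e-12] = 1.0
    As = A / row_norm[:, None]
    bs = b / row_norm

    lam = _dual_newton(h, As, bs, lb, ub)
    x, lam = _polish(h, As, bs, lb, ub, lam, kkt_tol=kkt_tol)

    def max_resid(xv: np.ndarray) -> tuple[int, float]:
        r = np.abs(A @ xv - b)
        w = int(np.argmax(r))
        return w, float(r[w])

    worst, resid = max_resid(x)
    if resid > residual_tol:
        x_fb = _sqp_fallback(h, As, bs, lb, ub)
        if x_fb is not None and max_resid(x_fb)[1] < resid:
            x = np.clip(x_fb, lb, ub)
        worst, resid = max_resid(x)
    if resid > residual_tol:
        label = row_labels[worst] if row_labels else f"row {worst}"
        raise InfeasibleError(
            f"equilibrium infeasible within bounds: residual {resid:.3e} at {label}",
            worst_row=worst,
            residual=resid,
        )
    return x, lam / row_norm
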