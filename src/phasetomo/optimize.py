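"""First-order solvers for smooth + non-smooth composite problems.

Engines behind the constrained and nonlinear retrieval methods:

* :func:`pgm_adaptive` — proximal gradient with spectral (Barzilai–Borwein)
  step sizes and nonmonotone backtracking line search,
* :func:`fista` — fast iterative shrinkage-thresholding with Nesterov
  momentum and gradient-based adaptive restart,
* :func:`admm_accel` — accelerated alternating direction method of
  multipliers with a residual-based restart rule, for problems whose
  x-update is solvable in closed form (Fourier-diagonal quadratics here).

Problems are posed as ``minimize f(x) + g(x)`` with smooth ``f`` given by
value/gradient callables and non-smooth ``g`` given by its proximal
operator (for constraint sets: the projection).  Gradients may be
hand-derived closures; :func:`check_grad` offers a central-finite-difference
sanity check used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "CompositeProblem",
    "SolverReport",
    "SolverFailure",
    "pgm_adaptive",
    "fista",
    "admm_accel",
    "check_grad",
]


class SolverFailure(RuntimeError):
    """Raised when a solver encounters non-finite values; carries the report."""

    def __init__(self, message: str, report: "SolverReport"):
        super().__init__(message)
        self.report = report


def _identity_prox(x: np.ndarray, step: float) -> np.ndarray:
    return x


@dataclass
class CompositeProblem:
    """A composite objective f(x) + g(x), g given through its prox."""

    smooth_value: Callable[[np.ndarray], float]
    smooth_grad: Callable[[np.ndarray], np.ndarray]
    prox: Callable[[np.ndarray, float], np.ndarray] = _identity_prox
    x0: Optional[np.ndarray] = None


@dataclass
class SolverReport:
    iterations: int = 0
    objective: list = field(default_factory=list)  # length iterations + 1
    steps: list = field(default_factory=list)
    converged: bool = False
    residuals: dict = field(default_factory=dict)


def _rdot(a: np.ndarray, b: np.ndarray) -> float:
    """Real inner product, valid for real and complex arrays."""
    return float(np.real(np.vdot(a, b)))


def _norm(a: np.ndarray) -> float:
    return float(np.linalg.norm(a.ravel()))


def _estimate_step(p: CompositeProblem, x0: np.ndarray, g0: np.ndarray) -> float:
    """Initial step 1/L from a secant estimate of the local Lipschitz constant."""
    gn = _norm(g0)
    if gn == 0:
        return 1.0
    scale = max(_norm(x0), 1.0)
    d = (1e-3 * scale / gn) * g0
    g1 = p.smooth_grad(x0 - d)
    dg = _norm(g1 - g0)
    if dg == 0:
        return 1.0
    return _norm(d) / dg


def pgm_adaptive(
    p: CompositeProblem,
    max_iter: int = 100,
    tol: float = 1e-6,
    window: int = 10,
) -> tuple[np.ndarray, SolverReport]:
    """Proximal gradient with BB steps and nonmonotone backtracking.

    The candidate step is the spectral (BB1) estimate
    ``⟨Δx, Δx⟩ / ⟨Δx, Δg⟩``; it is halved until the nonmonotone
    majorization (backtracking) condition

        f(x⁺) ≤ max(last ``window`` f values) + ⟨∇f(x), x⁺ − x⟩
                 + ‖x⁺ − x‖² / (2·step)

    holds — the composite-friendly form: a pure descent condition on f
    alone would be unsatisfiable whenever the prox step must climb the
    smooth term (e.g. projection onto an active constraint).  Stops when
    the relative iterate change drops below ``tol``.
    """
    x = np.array(p.x0, copy=True)
    rep = SolverReport()
    fx = p.smooth_value(x)
    if not np.isfinite(fx):
        raise SolverFailure("objective not finite at x0", rep)
    rep.objective.append(fx)
    g = p.smooth_grad(x)
    step = _estimate_step(p, x, g)

    for it in range(max_iter):
        f_ref = max(rep.objective[-window:])
        for _ in range(60):
            x_new = p.prox(x - step * g, step)
            dx = x_new - x
            f_new = p.smooth_value(x_new)
            if not np.isfinite(f_new):
                rep.iterations = it
                raise SolverFailure("non-finite objective during line search", rep)
            if f_new <= f_ref + _rdot(g, dx) + _rdot(dx, dx) / (2.0 * step) \
                    + 1e-12 * max(1.0, abs(f_ref)):
                break
            step *= 0.5
        else:
            rep.iterations = it
            raise SolverFailure("line search failed to find a decrease step", rep)

        g_new = p.smooth_grad(x_new)
        rep.objective.append(f_new)
        rep.steps.append(step)
        rel = _norm(dx) / max(_norm(x_new), 1e-30)
        # BB1 spectral step for the next iteration
        dg = g_new - g
        denom = _rdot(dx, dg)
        if denom > 0:
            step = _rdot(dx, dx) / denom
        x, g = x_new, g_new
        rep.iterations = it + 1
        if rel < tol:
            rep.converged = True
            break

    rep.residuals["rel_change"] = rel if rep.iterations else 0.0
    return x, rep


def fista(
    p: CompositeProblem,
    step: Optional[float] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    backtrack: bool = True,
    restart: bool = True,
) -> tuple[np.ndarray, SolverReport]:
    """FISTA with Nesterov momentum t_{k+1} = (1+√(1+4t_k²))/2.

    ``step`` defaults to a secant 1/L estimate; with ``backtrack`` the step
    is halved whenever the quadratic majorization at the extrapolated point
    is violated.  ``restart`` resets the momentum when the gradient mapping
    points uphill (adaptive restart), which restores monotone behaviour on
    strongly convex problems.
    """
    x = np.array(p.x0, copy=True)
    rep = SolverReport()
    rep.objective.append(p.smooth_value(x))
    if step is None:
        step = _estimate_step(p, x, p.smooth_grad(x))
    x_prev = x
    t = 1.0

    for it in range(max_iter):
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x + ((t - 1.0) / t_next) * (x - x_prev)
        fy = p.smooth_value(y)
        gy = p.smooth_grad(y)
        for _ in range(60):
            x_new = p.prox(y - step * gy, step)
            d = x_new - y
            f_new = p.smooth_value(x_new)
            if not np.isfinite(f_new):
                rep.iterations = it
                raise SolverFailure("non-finite objective in FISTA line search", rep)
            if (not backtrack) or f_new <= fy + _rdot(gy, d) + _rdot(d, d) / (2.0 * step) \
                    + 1e-15 * max(1.0, abs(fy)):
                break
            step *= 0.5
        if restart and _rdot(y - x_new, x_new - x) > 0:
            t_next = 1.0  # adaptive restart: kill the momentum
        rep.objective.append(f_new)
        rep.steps.append(step)
        rel = _norm(x_new - x) / max(_norm(x_new), 1e-30)
        x_prev, x, t = x, x_new, t_next
        rep.iterations = it + 1
        if rel < tol:
            rep.converged = True
            break

    return x, rep


def admm_accel(
    x_update: Callable[[np.ndarray, float], np.ndarray],
    prox_g: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    rho: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    eta: float = 0.999,
    balance: bool = True,
) -> tuple[np.ndarray, SolverReport]:
    """Accelerated ADMM for ``minimize f(x) + g(z)  s.t.  x = z``.

    Parameters
    ----------
    x_update : callable ``(v, rho) -> argmin_x f(x) + (rho/2)‖x − v‖²`` —
        the closed-form proximal step of the data term (Fourier-diagonal
        systems in this toolbox).
    prox_g : projection/prox of g (step folded in by the caller if needed).
    x0 : initial iterate for z.
    rho : augmented-Lagrangian penalty (> 0).
    eta : restart threshold — momentum is reset whenever the combined
        residual fails to decrease by factor ``eta``.
    balance : double/halve rho (rescaling the dual) when primal and dual
        residual norms differ by more than 10×.

    Returns the final ``z`` iterate, which satisfies the constraints exactly
    when ``prox_g`` is a projection.
    """
    if rho <= 0:
        raise ValueError(f"rho must be positive, got {rho}")
    z = np.array(x0, copy=True)
    u = np.zeros_like(z)
    z_hat, u_hat = z.copy(), u.copy()
    t = 1.0
    c_prev = np.inf
    rep = SolverReport()
    scale = max(_norm(z), 1.0)

    for it in range(max_iter):
        x = x_update(z_hat - u_hat, rho)
        z_new = prox_g(x + u_hat)
        u_new = u_hat + x - z_new
        r_primal = _norm(x - z_new)
        s_dual = rho * _norm(z_new - z_hat)
        c = rho * _norm(u_new - u_hat) ** 2 + rho * _norm(z_new - z_hat) ** 2

        if c < eta * c_prev:
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z_hat = z_new + ((t - 1.0) / t_next) * (z_new - z)
            u_hat = u_new + ((t - 1.0) / t_next) * (u_new - u)
            t = t_next
        else:  # restart
            t = 1.0
            z_hat, u_hat = z.copy(), u.copy()
            c = c_prev / eta
        z, u, c_prev = z_new, u_new, c

        rep.steps.append(rho)
        rep.iterations = it + 1
        rep.residuals = {"primal": r_primal, "dual": s_dual}
        if r_primal < tol * scale and s_dual < tol * scale:
            rep.converged = True
            break
        if balance and r_primal > 10.0 * s_dual:
            rho *= 2.0
            u = u / 2.0
            u_hat = u_hat / 2.0
        elif balance and s_dual > 10.0 * r_primal:
            rho /= 2.0
            u = u * 2.0
            u_hat = u_hat * 2.0

    return z, rep


def check_grad(
    value: Callable[[np.ndarray], float],
    grad: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    rel_step: float = 1e-6,
    n_dirs: int = 8,
    rng: Optional[np.random.Generator] = None,
) -> float:
    """Max relative error of ``grad`` against central finite differences.

    Probes ``n_dirs`` random directions with step ``rel_step·scale``; cheap
    enough to run inside tests on small images.
    """
    rng = rng or np.random.default_rng(0)
    g = grad(x)
    scale = max(_norm(x), 1.0)
    h = rel_step * scale
    worst = 0.0
    for _ in range(n_dirs):
        d = rng.standard_normal(x.shape)
        d /= _norm(d)
        fd = (value(x + h * d) - value(x - h * d)) / (2.0 * h)
        an = _rdot(g, d)
        worst = max(worst, abs(fd - an) / max(abs(fd), abs(an), 1e-12))
    return worst
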