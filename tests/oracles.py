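"""Independent oracles for cross-checking the package's computations.

Everything here deliberately avoids the code paths it validates:
steady states by bisection and by ODE time-stepping instead of the
closed-form quadratic, maxima by brute-force grid search instead of
refined scalar optimization, closed-loop fixed points by damped
fixed-point iteration instead of bracketed root finding.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import solve_ivp


def input_value(kind: str, C: float, C0: float = 0.0, Cmax: float = 1.0) -> float:
    if kind == "proportional":
        return C
    if kind == "offset":
        return C + C0
    return C / (1.0 + (C / Cmax) ** 2)


def balance_residual(beta, gamma, k1, k2, P, C, x) -> float:
    return beta * P * k1 / (k1 + x) - gamma * (1.0 - C) * x / (x + k2)


def x_by_bisection(beta, gamma, k1, k2, P, C, tol=1e-14) -> float:
    """Steady-state x by sign-change bisection with a grown bracket."""
    if P == 0.0:
        return 0.0
    lo, hi = 0.0, 1.0
    while balance_residual(beta, gamma, k1, k2, P, C, hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("no bracket")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if balance_residual(beta, gamma, k1, k2, P, C, mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    return 0.5 * (lo + hi)


def x_by_ode(beta, gamma, k1, k2, P, C, t_end=2000.0) -> float:
    """Steady-state x by integrating dx/dt = import - consumption."""
    def rhs(_, x):
        return [balance_residual(beta, gamma, k1, k2, P, C, x[0])]
    sol = solve_ivp(rhs, (0.0, t_end), [1e-6], rtol=1e-12, atol=1e-14)
    return float(sol.y[0, -1])


def mu_closed_form_matched_k(beta, gamma, P, C) -> float:
    """mu(C) for k1 = k2: flux balance collapses to a Monod-like form."""
    denom = beta * P + gamma * (1.0 - C)
    if denom == 0.0:
        return 0.0
    return beta * gamma * P * (1.0 - C) / denom


def c_opt_closed_form(beta, gamma) -> float:
    """O-curve maximizer for proportional input and k1 = k2."""
    return math.sqrt(gamma) / (math.sqrt(beta) + math.sqrt(gamma))


def c_opt_brute_force(mu_of_c, n=10**6) -> tuple[float, float]:
    """Maximum of mu(C) by dense grid evaluation."""
    grid = np.linspace(1e-9, 1.0 - 1e-9, n)
    mu = mu_of_c(grid)
    i = int(np.argmax(mu))
    return float(grid[i]), float(mu[i])


def closed_loop_by_fixed_point(beta, gamma, k1, k2, kf, input_kind,
                               C0=0.0, Cmax=1.0, damping=0.5,
                               n_iter=20000) -> float:
    """Closed-loop C by damped fixed-point iteration C <- f(x(C))."""
    C = 0.5
    for _ in range(n_iter):
        P = input_value(input_kind, C, C0, Cmax)
        x = x_by_bisection(beta, gamma, k1, k2, P, C)
        C_new = 1.0 / (1.0 + x / kf)
        C = damping * C_new + (1.0 - damping) * C
    return C
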