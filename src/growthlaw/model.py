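"""Minimal proteome-allocation model of carbon catabolism.

The cell's proteome is split into a carbon-catabolic sector ``C``
(uptake and catabolism, under CRP control) and a biomass sector
``R = 1 - C`` (ribosomes and everything else).  Internal carbon ``x``
(the pool of catabolites/precursors) is imported at maximal rate
``beta`` by the sector-C machinery, with allosteric product inhibition
of the pumps (half-inhibition constant ``k1``), and consumed by biomass
production at maximal rate ``gamma`` with Michaelis-Menten saturation
(half-saturation ``k2``):

    import(x, C)      = beta * P(C) * k1 / (k1 + x)
    consumption(x, C) = gamma * (1 - C) * x / (x + k2)
    mu                = gamma * (1 - C) * x / (x + k2)

``P(C)`` is the input function of the limiting uptake enzyme: for most
sugar systems expression is proportional to the CRP-controlled sector
(``P(C) = C``), but some systems have CRP-independent basal expression
(``P(C) = C + C0``) or a non-monotonic input function produced by an
incoherent feed-forward loop (``P(C) = C / (1 + (C/Cmax)^2)``).

At steady state import equals consumption, which is a quadratic in
``x`` and solved in closed form.  Sweeping ``C`` at fixed ``beta``
yields the O-curve mu(C) ("open loop"); its maximum is the best growth
the cell could achieve by tuning CRP activity.  The endogenous feedback
— internal carbon repressing cAMP and hence the C-sector, modelled as
``C = f(x) = 1 / (1 + x/kf)`` — picks one point per ``beta``; the locus
of those points across carbon qualities is the C-line ("closed loop",
the growth law).  Feedback control is *robustly optimal* — the C-line
passes through every O-curve maximum, for all beta — exactly when
``P(C) = C`` and ``k1 = k2 = kf``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "InputFunction",
    "ModelParams",
    "SteadyState",
    "ModelOCurve",
    "eval_input_function",
    "steady_state_x",
    "growth_rate",
    "model_ocurve",
    "closed_loop_state",
    "model_cline",
    "optimality_gap",
    "mu_curve",
]

InputKind = Literal["proportional", "offset", "nonmonotonic"]


@dataclass(frozen=True)
class InputFunction:
    """Expression of the limiting uptake enzyme as a function of C.

    kind
        ``proportional``  -> P(C) = C
        ``offset``        -> P(C) = C + C0   (basal, CRP-independent expression)
        ``nonmonotonic``  -> P(C) = C / (1 + (C/Cmax)^2)   (I-FFL shape)
    C0
        Basal expression level (dimensionless, offset kind only).
    Cmax
        Location of the expression peak (nonmonotonic kind only).
    """

    kind: InputKind = "proportional"
    C0: float = 0.0
    Cmax: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("proportional", "offset", "nonmonotonic"):
            raise ValueError(f"unknown input-function kind: {self.kind!r}")
        if self.C0 < 0:
            raise ValueError("basal expression C0 must be >= 0")
        if self.Cmax <= 0:
            raise ValueError("peak location Cmax must be > 0")

    def __call__(self, C):
        return eval_input_function(self, C)


def eval_input_function(input: InputFunction, C):
    """Evaluate P(C) for C in [0, 1] (scalar or array)."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0) or np.any(C > 1):
        raise ValueError("C is a proteome fraction and must lie in [0, 1]")
    if input.kind == "proportional":
        out = C
    elif input.kind == "offset":
        out = C + input.C0
    else:
        out = C / (1.0 + (C / input.Cmax) ** 2)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the allocation model.

    beta
        Maximal carbon import rate (time^-1); condition/carbon-source
        dependent — high for good carbon sources.
    gamma
        Maximal biomass production rate (time^-1).  ``gamma = 1`` sets
        the time unit; only rate ratios are identifiable.
    k1
        Half-inhibition constant of import by internal carbon x.
    k2
        Half-saturation constant of biomass production by x.
    kf
        Half-inhibition constant of the C-sector feedback by x.
    input
        Input function P(C) of the limiting uptake enzyme.

    All half-constants share x's (arbitrary) concentration unit, so
    only their ratios matter; expressing k1 and kf relative to k2 = 1
    is the conventional normalization.
    """

    beta: float
    gamma: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    kf: float = 1.0
    input: InputFunction = field(default_factory=InputFunction)

    def __post_init__(self) -> None:
        for name in ("beta", "gamma", "k1", "k2", "kf"):
            v = getattr(self, name)
            if not (v > 0) or not math.isfinite(v):
                if name == "beta" and v == 0:
                    continue  # beta = 0 (no carbon) is a meaningful edge case
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class SteadyState:
    """One steady state of the closed-loop (feedback-controlled) system."""

    C: float
    x: float
    mu: float

    @property
    def R(self) -> float:
        return 1.0 - self.C

    def __post_init__(self) -> None:
        if not (0.0 <= self.C <= 1.0):
            raise ValueError("C must lie in [0, 1]")
        if self.x < 0 or self.mu < 0:
            raise ValueError("x and mu must be non-negative")


@dataclass(frozen=True)
class ModelOCurve:
    """Growth rate as a function of C-sector size at fixed parameters."""

    C_grid: np.ndarray
    mu_values: np.ndarray
    C_opt: float
    mu_opt: float
    no_interior_maximum: bool = False


def steady_state_x(params: ModelParams, C: float) -> float:
    """Steady-state internal carbon at imposed C-sector size.

    Solves the flux balance

        beta * P(C) * k1 / (k1 + x) = gamma * (1 - C) * x / (x + k2)

    which is a quadratic in x; the unique non-negative root is returned
    in closed form (numerically stable variant).  ``P(C) = 0`` gives
    x = 0 (nothing is imported).  ``C = 1`` with positive import has no
    finite steady state: x grows without bound because the biomass
    sector that consumes it is empty.
    """
    P = eval_input_function(params.input, C)
    A = params.beta * P * params.k1          # import numerator
    B = params.gamma * (1.0 - C)             # consumption capacity
    if A == 0.0:
        return 0.0
    if B == 0.0:
        raise ValueError(
            "C = 1 with positive import: biomass sector is empty, "
            "internal carbon has no finite steady state"
        )
    # B x^2 + (B k1 - A) x - A k2 = 0
    b = B * params.k1 - A
    disc = math.sqrt(b * b + 4.0 * B * A * params.k2)
    if b <= 0:
        x = (-b + disc) / (2.0 * B)
    else:  # avoid catastrophic cancellation when b > 0
        x = 2.0 * A * params.k2 / (b + disc)
    return max(x, 0.0)


def growth_rate(params: ModelParams, C: float) -> float:
    """Steady-state growth rate mu(C) — one point of the O-curve.

    mu = gamma * (1 - C) * x / (x + k2) with x the steady-state
    internal carbon.  Vanishes at both ends: C = 0 means no uptake
    machinery (for P(0) = 0), C = 1 means no biomass machinery.
    """
    if not (0.0 <= C <= 1.0):
        raise ValueError("C must lie in [0, 1]")
    if C == 1.0:
        return 0.0
    x = steady_state_x(params, C)
    if x == 0.0:
        return 0.0
    return params.gamma * (1.0 - C) * x / (x + params.k2)


def mu_curve(params: ModelParams, C) -> np.ndarray:
    """Vectorized O-curve evaluation: mu at each C of an array.

    Same closed-form quadratic solution as :func:`steady_state_x`,
    evaluated with array arithmetic (the stable root variant is chosen
    elementwise).  Used by grid sweeps and curve fitting.
    """
    C = np.asarray(C, dtype=float)
    P = np.asarray(eval_input_function(params.input, C), dtype=float)
    A = params.beta * P * params.k1
    B = params.gamma * (1.0 - C)
    mu = np.zeros_like(C)
    ok = (A > 0) & (B > 0)
    if np.any(ok):
        b = B[ok] * params.k1 - A[ok]
        disc = np.sqrt(b * b + 4.0 * B[ok] * A[ok] * params.k2)
        x = np.where(b <= 0, (-b + disc) / (2.0 * B[ok]),
                     2.0 * A[ok] * params.k2 / (b + disc))
        mu[ok] = params.gamma * (1.0 - C[ok]) * x / (x + params.k2)
    return mu if mu.ndim else float(mu)


def model_ocurve(params: ModelParams, n_grid: int = 201) -> ModelOCurve:
    """Evaluate the O-curve mu(C) on a grid and locate its maximum.

    The maximum is refined from the best grid point by bounded scalar
    minimization (Brent) to |dC| <= 1e-8, so it is not limited to grid
    resolution.  A flat curve (all mu = 0, e.g. beta = 0) is reported
    with ``no_interior_maximum=True``.
    """
    if n_grid < 25:
        raise ValueError("n_grid must be >= 25")
    eps = 1e-9
    C_grid = np.linspace(eps, 1.0 - eps, n_grid)
    mu_values = mu_curve(params, C_grid)
    if np.all(mu_values == 0.0):
        return ModelOCurve(C_grid, mu_values, math.nan, 0.0,
                           no_interior_maximum=True)
    i = int(np.argmax(mu_values))
    lo = C_grid[max(i - 1, 0)]
    hi = C_grid[min(i + 1, n_grid - 1)]
    res = minimize_scalar(lambda c: -growth_rate(params, c),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    C_opt = float(res.x)
    mu_opt = float(-res.fun)
    return ModelOCurve(C_grid, mu_values, C_opt, mu_opt)


def _feedback_x(params: ModelParams, C: float) -> float:
    """Invert C = f(x) = 1/(1 + x/kf): the x consistent with feedback."""
    return params.kf * (1.0 - C) / C


def closed_loop_state(params: ModelParams) -> SteadyState:
    """Steady state of the full system with the cAMP-CRP feedback closed.

    Solves jointly the flux balance and the regulatory constraint
    C = f(x) = 1/(1 + x/kf), by bracketed root finding on C in (0, 1):
    substituting the feedback relation x = kf (1-C)/C into the
    import-minus-consumption residual gives a function that is negative
    as C -> 0 (x huge, import fully inhibited) and positive as C -> 1
    (x -> 0, no consumption), so a fixed point always exists for
    beta * P(1) > 0.
    """
    def residual(C: float) -> float:
        x = _feedback_x(params, C)
        P = eval_input_function(params.input, C)
        imp = params.beta * P * params.k1 / (params.k1 + x)
        cons = params.gamma * (1.0 - C) * x / (x + params.k2)
        return imp - cons

    lo, hi = 1e-9, 1.0 - 1e-9
    rlo, rhi = residual(lo), residual(hi)
    if not (rlo < 0 < rhi):
        raise ValueError(
            "no closed-loop fixed point with C in (0, 1) for "
            f"beta={params.beta}, gamma={params.gamma}, input={params.input.kind}"
        )
    C_ss = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-15, maxiter=200)
    x_ss = _feedback_x(params, C_ss)
    mu_ss = params.gamma * (1.0 - C_ss) * x_ss / (x_ss + params.k2)
    return SteadyState(C=float(C_ss), x=float(x_ss), mu=float(mu_ss))


def model_cline(params_base: ModelParams,
                beta_values: Sequence[float]) -> list[SteadyState]:
    """Closed-loop (C, mu) locus across carbon qualities — the modelled C-line.

    One steady state per beta, ordered as given (conventionally by
    beta).  The locus resembles a straight line with some curvature at
    high C; no linearity is enforced.
    """
    if any(b <= 0 for b in beta_values):
        raise ValueError("beta values must be positive")
    from dataclasses import replace
    return [closed_loop_state(replace(params_base, beta=b))
            for b in beta_values]


def optimality_gap(params: ModelParams) -> float:
    """Relative growth cost of feedback control: (mu_opt - mu_cl)/mu_cl.

    Zero (to numerical precision) exactly in the robustly optimal
    regime (proportional input, k1 = k2 = kf); strictly positive when
    the input function has an offset or is non-monotonic, or when the
    feedback constant kf is mismatched.  Never negative: the O-curve
    maximum is a global maximum over C.
    """
    ss = closed_loop_state(params)
    if ss.mu == 0.0:
        raise ValueError("closed-loop growth rate is zero; gap undefined")
    oc = model_ocurve(params)
    if oc.no_interior_maximum:
        raise ValueError("flat O-curve; gap undefined")
    return max((oc.mu_opt - ss.mu) / ss.mu, 0.0)
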