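"""The glucose–insulin–β-cell ODE system and its steady states.

The model couples plasma glucose G (mM), plasma insulin I (nM) and β-cell
mass β (arbitrary units):

    dG/dt = R0 − (EG0 + SP·I)·G
    dI/dt = β·σ0/(1 + Sβ·I) · G²/(α + G²) − k·I
    dβ/dt = (−d0 + r1·G − r2·G²)·β

The factor 1/(1 + Sβ·I) is an autocrine negative feedback of insulin on
its own secretion, mediated by the β-cell insulin receptor; Sβ = 0 removes
it and recovers the classical Topp system.  Because β-cell mass changes on
a timescale of days while G and I settle in minutes, glucose-tolerance-test
simulations use the two-equation "fast GI" reduction with β held constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .params import ModelParams

__all__ = [
    "ModelState",
    "Trajectory",
    "secretion_rate",
    "derivatives",
    "integrate",
    "steady_state_fast",
    "steady_state_full",
    "full_steady_state_roots",
    "clamp_steady_insulin",
    "SingularInhibitionError",
    "SteadyStateError",
    "IntegrationError",
]

Mode = Literal["full", "fast"]


class SingularInhibitionError(ValueError):
    """The inhibition factor 1/(1+Sβ·I) is singular or negative."""


class SteadyStateError(RuntimeError):
    """No steady state could be located under the stated conditions."""


class IntegrationError(RuntimeError):
    """The ODE integrator failed or the state exceeded the blow-up bound."""


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state: glucose (mM), insulin (nM), β mass."""

    G: float
    I: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("G", "I", "beta"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.G, self.I, self.beta], dtype=float)


@dataclass(frozen=True)
class Trajectory:
    """Time-stamped solution of the GIβ system.

    ``mode`` records whether β evolved ("full") or was held constant
    ("fast").  Columns are aligned: ``G[i]`` etc. correspond to ``times[i]``.
    """

    times: np.ndarray
    G: np.ndarray
    I: np.ndarray
    beta: np.ndarray
    mode: Mode

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be a strictly increasing 1-D grid")
        for name in ("G", "I", "beta"):
            if len(getattr(self, name)) != len(t):
                raise ValueError(f"{name} must align with times")
        if self.mode == "fast" and not np.allclose(self.beta, self.beta[0], rtol=0, atol=0):
            raise ValueError("fast-mode trajectory must hold beta constant")

    def state_at(self, i: int) -> ModelState:
        return ModelState(float(self.G[i]), float(self.I[i]), float(self.beta[i]))

    def to_frame(self):
        """Trajectory as a DataFrame with the export column schema."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "glucose_mM": self.G,
                "insulin_nM": self.I,
                "beta_mass": self.beta,
            }
        )


def _inhibition(I: float, params: ModelParams) -> float:
    denom = 1.0 + params.Sbeta * I
    if denom <= 0.0:
        raise SingularInhibitionError(
            f"singular inhibition factor: 1 + Sbeta*I = {denom} <= 0"
        )
    return 1.0 / denom


def secretion_rate(G: float, I: float, beta: float, params: ModelParams) -> float:
    """Insulin secretion rate β·σ0/(1+Sβ·I)·G²/(α+G²) in nM·min⁻¹.

    With Sbeta = 0 this is exactly the Topp secretion term.  Raises
    :class:`SingularInhibitionError` if 1 + Sβ·I ≤ 0.
    """
    if G < 0:
        raise ValueError(f"G must be >= 0, got {G}")
    # evaluation order matches the classical Topp term so that Sbeta = 0
    # (inhibition factor exactly 1.0) reduces to it bitwise
    return beta * params.sigma0 * G ** 2 / (params.alpha + G ** 2) * _inhibition(I, params)


def derivatives(
    state: ModelState, params: ModelParams, mode: Mode = "full"
) -> Tuple[float, float, float]:
    """Right-hand side (dG/dt, dI/dt, dβ/dt) at a state.

    In "fast" mode the β component is exactly 0 (β-cell mass frozen).
    """
    if mode not in ("full", "fast"):
        raise ValueError(f"mode must be 'full' or 'fast', got {mode!r}")
    G, I, beta = state.G, state.I, state.beta
    dG = params.R0 - (params.EG0 + params.SP * I) * G
    dI = secretion_rate(G, I, beta, params) - params.k * I
    if mode == "fast":
        dbeta = 0.0
    else:
        dbeta = (-params.d0 + params.r1 * G - params.r2 * G * G) * beta
    return (dG, dI, dbeta)


def integrate(
    params: ModelParams,
    init: ModelState,
    t_grid: Sequence[float],
    mode: Mode = "full",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    blowup_bound: float = 1e6,
) -> Trajectory:
    """Integrate the system over a strictly increasing time grid (minutes).

    Uses an adaptive stiff-capable solver (LSODA) with dense output
    sampled onto ``t_grid``.  Raises :class:`IntegrationError` on solver
    failure or if any state component exceeds ``blowup_bound``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D grid")
    if mode not in ("full", "fast"):
        raise ValueError(f"mode must be 'full' or 'fast', got {mode!r}")

    def rhs(_t: float, y: np.ndarray) -> list:
        G, I, beta = y
        dG = params.R0 - (params.EG0 + params.SP * I) * G
        denom = 1.0 + params.Sbeta * I
        if denom <= 0.0:
            raise SingularInhibitionError(
                f"singular inhibition factor during integration: 1+Sbeta*I={denom}"
            )
        dI = beta * params.sigma0 * G ** 2 / (params.alpha + G ** 2) / denom - params.k * I
        if mode == "fast":
            return [dG, dI, 0.0]
        dbeta = (-params.d0 + params.r1 * G - params.r2 * G * G) * beta
        return [dG, dI, dbeta]

    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        init.as_array(),
        method="LSODA",
        t_eval=t,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed: {sol.message}")
    y = sol.y
    if not np.all(np.isfinite(y)) or np.any(np.abs(y) > blowup_bound):
        raise IntegrationError(
            f"state blow-up: component exceeded bound {blowup_bound:g}"
        )
    beta_arr = y[2]
    if mode == "fast":
        # LSODA keeps a zero-derivative component bitwise constant, but be
        # explicit: the reduction holds beta frozen by construction.
        beta_arr = np.full_like(beta_arr, init.beta)
    return Trajectory(times=t, G=y[0], I=y[1], beta=beta_arr, mode=mode)


def clamp_steady_insulin(params: ModelParams, G_clamp: float, beta_fixed: float) -> float:
    """Steady-state plasma insulin (nM) at a fixed clamped glucose level.

    Solves β·σ0·Gf/(1+Sβ·I) = k·I with Gf = G²/(α+G²), i.e. the positive
    root of k·Sβ·I² + k·I − β·σ0·Gf = 0.  This is the model of a
    hyperglycemic clamp: glucose held constant by exogenous infusion while
    insulin relaxes to secretion–clearance balance.
    """
    if G_clamp <= 0:
        raise ValueError(f"G_clamp must be > 0, got {G_clamp}")
    if params.k <= 0:
        raise ValueError("k must be > 0 for a clamp steady state")
    if beta_fixed < 0:
        raise ValueError(f"beta_fixed must be >= 0, got {beta_fixed}")
    Gf = G_clamp * G_clamp / (params.alpha + G_clamp * G_clamp)
    s = beta_fixed * params.sigma0 * Gf
    if params.Sbeta == 0.0:
        return s / params.k
    a = params.k * params.Sbeta
    b = params.k
    c = -s
    disc = b * b - 4.0 * a * c
    # c <= 0 so disc >= b^2 and the root below is the unique nonnegative one.
    return (-b + math.sqrt(disc)) / (2.0 * a)


def steady_state_fast(
    params: ModelParams,
    beta_fixed: float,
    G_bracket: Tuple[float, float] = (1e-9, None),
) -> Tuple[float, float]:
    """Steady state (G*, I*) of the fast GI model at fixed β-cell mass.

    At steady state the insulin equation gives I*(G) =
    ``clamp_steady_insulin`` at that glucose, so G* is the unique root of
    R0 − (EG0 + SP·I*(G))·G on (0, R0/EG0]; the residual of both equations
    at the returned point is below 1e-9 in scaled units.
    """
    lo, hi = G_bracket
    if hi is None:
        # Upper bound on G*: with I >= 0, dG/dt <= R0 - EG0*G.
        hi = params.R0 / params.EG0 if params.EG0 > 0 else max(10.0 * params.R0 / max(params.SP, 1e-12), 100.0)

    def g_residual(G: float) -> float:
        I = clamp_steady_insulin(params, G, beta_fixed)
        return params.R0 - (params.EG0 + params.SP * I) * G

    flo, fhi = g_residual(lo), g_residual(hi)
    if flo * fhi > 0:
        raise SteadyStateError(
            f"no steady state found in bracket ({lo:g}, {hi:g}): "
            f"residuals {flo:g}, {fhi:g} do not change sign"
        )
    G_star = brentq(g_residual, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    I_star = clamp_steady_insulin(params, G_star, beta_fixed)
    return (float(G_star), float(I_star))


def full_steady_state_roots(params: ModelParams) -> Tuple[float, float]:
    """Both glucose roots of the β-cell net-growth quadratic.

    β-cell mass is stationary where −d0 + r1·G − r2·G² = 0; the two roots
    (lower first) depend only on d0, r1, r2 — not on SP or Sβ.
    """
    disc = params.r1 * params.r1 - 4.0 * params.r2 * params.d0
    if disc < 0:
        raise SteadyStateError(
            "no interior steady state: r1^2 < 4*r2*d0 (discriminant negative)"
        )
    if params.r2 == 0:
        if params.r1 == 0:
            raise SteadyStateError("no interior steady state: r1 = r2 = 0")
        g = params.d0 / params.r1
        return (g, math.inf)
    sq = math.sqrt(disc)
    g_lo = (params.r1 - sq) / (2.0 * params.r2)
    g_hi = (params.r1 + sq) / (2.0 * params.r2)
    return (g_lo, g_hi)


def steady_state_full(
    params: ModelParams, branch: Literal["lower", "upper"] = "lower"
) -> Tuple[float, float, float]:
    """Interior steady state (G*, I*, β*) of the full GIβ model.

    G* solves the β-equation quadratic (hence is independent of SP and
    Sβ); I* then follows from the glucose equation and β* from the insulin
    equation.  The lower-G root — the physiologically stable branch — is
    returned by default.
    """
    g_lo, g_hi = full_steady_state_roots(params)
    G = g_lo if branch == "lower" else g_hi
    if not math.isfinite(G) or G <= 0:
        raise SteadyStateError(f"steady-state glucose root not positive: {G}")
    if params.SP <= 0:
        raise SteadyStateError("SP must be > 0 to solve the glucose equation for I*")
    I = (params.R0 / G - params.EG0) / params.SP
    if I < 0:
        raise SteadyStateError(
            f"steady-state insulin negative (I*={I:g}): R0/G* < EG0"
        )
    Gf = G * G / (params.alpha + G * G)
    if params.sigma0 <= 0 or Gf <= 0:
        raise SteadyStateError("sigma0 and G* must be positive to solve for beta*")
    beta = params.k * I * (1.0 + params.Sbeta * I) / (params.sigma0 * Gf)
    return (float(G), float(I), float(beta))
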