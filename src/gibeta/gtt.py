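"""In-silico glucose tolerance tests and AUGC-surface inversion of S_P.

A simulated GTT starts the fast GI model (β frozen at a reference value)
at its steady state, applies an instantaneous glucose bolus (+20 mM by
default) and integrates the response.  The area under the glucose curve
(AUGC) as a function of (Sβ, S_P) forms a numerical map; experimental
AUGC bands (mean ± SEM) intersected with an Sβ band invert the map into
an interval of compatible peripheral insulin sensitivities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import IntegrationError, ModelState, SteadyStateError, integrate, steady_state_fast
from .params import ModelParams

__all__ = [
    "GTTCurve",
    "AUGCSurface",
    "SPEstimate",
    "simulate_gtt",
    "augc",
    "auic",
    "build_augc_surface",
    "invert_sp",
]

DEFAULT_DURATION_MIN = 60.0
DEFAULT_BOLUS_MM = 20.0


@dataclass(frozen=True)
class GTTCurve:
    """A glucose-tolerance-test curve (times in minutes post-bolus)."""

    times: np.ndarray
    glucose: np.ndarray
    insulin: Optional[np.ndarray]
    bolus: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        g = np.asarray(self.glucose, dtype=float)
        if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing with >= 2 points")
        if t[0] != 0:
            raise ValueError("times must start at 0 (bolus instant)")
        if len(g) != len(t) or np.any(g <= 0):
            raise ValueError("glucose must align with times and be positive")
        if self.bolus < 0:
            raise ValueError("bolus must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "glucose", g)
        if self.insulin is not None:
            ins = np.asarray(self.insulin, dtype=float)
            if len(ins) != len(t):
                raise ValueError("insulin must align with times")
            object.__setattr__(self, "insulin", ins)


@dataclass(frozen=True)
class AUGCSurface:
    """Glucose and insulin AUCs on an (Sβ, S_P) grid.

    ``augc[i, j]`` is the glucose AUC at ``sbeta_grid[i]``, ``sp_grid[j]``
    (mM·min); ``auic`` likewise for insulin (nM·min).
    """

    sbeta_grid: np.ndarray
    sp_grid: np.ndarray
    augc: np.ndarray
    auic: np.ndarray

    def __post_init__(self) -> None:
        sb = np.asarray(self.sbeta_grid, dtype=float)
        sp = np.asarray(self.sp_grid, dtype=float)
        if np.any(np.diff(sb) <= 0) or np.any(np.diff(sp) <= 0):
            raise ValueError("grids must be strictly increasing")
        for name in ("augc", "auic"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (len(sb), len(sp)) or not np.all(np.isfinite(a)):
                raise ValueError(f"{name} must be a complete (len(sbeta), len(sp)) grid")
        if np.any(np.asarray(self.augc) <= 0):
            raise ValueError("augc must be positive everywhere")

    def to_frame(self) -> pd.DataFrame:
        sb, sp = np.meshgrid(self.sbeta_grid, self.sp_grid, indexing="ij")
        return pd.DataFrame(
            {
                "sbeta": sb.ravel(),
                "sp": sp.ravel(),
                "augc_mM_min": np.asarray(self.augc).ravel(),
                "auic_nM_min": np.asarray(self.auic).ravel(),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AUGCSurface":
        sb = np.unique(df["sbeta"].to_numpy())
        sp = np.unique(df["sp"].to_numpy())
        shape = (len(sb), len(sp))
        piv = df.sort_values(["sbeta", "sp"])
        return cls(
            sbeta_grid=sb,
            sp_grid=sp,
            augc=piv["augc_mM_min"].to_numpy().reshape(shape),
            auic=piv["auic_nM_min"].to_numpy().reshape(shape),
        )


@dataclass(frozen=True)
class SPEstimate:
    """An S_P interval compatible with AUGC and Sβ uncertainty bands."""

    lo: float
    hi: float
    augc_mean: float
    augc_sem: float
    sbeta_mean: float
    sbeta_sem: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("interval must satisfy lo <= hi")

    def to_dict(self) -> dict:
        return {
            "sp_lo": self.lo,
            "sp_hi": self.hi,
            "augc_mean_mM_min": self.augc_mean,
            "augc_sem_mM_min": self.augc_sem,
            "sbeta_mean_nM_inv": self.sbeta_mean,
            "sbeta_sem_nM_inv": self.sbeta_sem,
        }


def simulate_gtt(
    params: ModelParams,
    beta_fixed: float,
    bolus: float = DEFAULT_BOLUS_MM,
    duration: float = DEFAULT_DURATION_MIN,
    t_grid: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GTTCurve:
    """Simulate a glucose tolerance test with the fast GI model.

    β-cell mass is held at ``beta_fixed``.  The initial condition is the
    fast-model steady state with the bolus added to glucose at t = 0;
    insulin starts at its steady-state value.
    """
    if bolus < 0:
        raise ValueError("bolus must be >= 0")
    if t_grid is None:
        t_grid = np.arange(0.0, duration + 0.5, 1.0)
    G_star, I_star = steady_state_fast(params, beta_fixed)
    init = ModelState(G=G_star + bolus, I=I_star, beta=beta_fixed)
    traj = integrate(params, init, t_grid, mode="fast", rtol=rtol, atol=atol)
    return GTTCurve(times=traj.times, glucose=traj.G, insulin=traj.I, bolus=bolus)


def _trapz(values: np.ndarray, times: np.ndarray, baseline: float) -> float:
    return float(np.trapezoid(np.asarray(values, dtype=float) - baseline, times))


def augc(curve: GTTCurve, baseline_subtract: bool = False) -> float:
    """Trapezoidal area under the glucose curve (mM·min).

    Total (non-baseline-subtracted) by default; with
    ``baseline_subtract`` the final glucose value is treated as baseline.
    """
    base = float(curve.glucose[-1]) if baseline_subtract else 0.0
    return _trapz(curve.glucose, curve.times, base)


def auic(curve: GTTCurve, baseline_subtract: bool = False) -> float:
    """Trapezoidal area under the insulin curve (nM·min)."""
    if curve.insulin is None:
        raise ValueError("curve carries no insulin samples")
    base = float(curve.insulin[-1]) if baseline_subtract else 0.0
    return _trapz(curve.insulin, curve.times, base)


def build_augc_surface(
    template: ModelParams,
    sbeta_grid: Sequence[float],
    sp_grid: Sequence[float],
    beta_fixed: float,
    bolus: float = DEFAULT_BOLUS_MM,
    duration: float = DEFAULT_DURATION_MIN,
) -> AUGCSurface:
    """Map (Sβ, S_P) to glucose and insulin AUCs of a simulated GTT.

    Per cell the fast-model steady state is recomputed (with the shared
    reference β mass) and a GTT simulated.  Failures are reported with
    the offending cell coordinates.
    """
    sb = np.asarray(sbeta_grid, dtype=float)
    sp = np.asarray(sp_grid, dtype=float)
    if sb.size == 0 or sp.size == 0:
        raise ValueError("grids must be nonempty")
    A = np.empty((len(sb), len(sp)))
    B = np.empty_like(A)
    for i, s_b in enumerate(sb):
        for j, s_p in enumerate(sp):
            p = template.replace(Sbeta=float(s_b), SP=float(s_p))
            try:
                curve = simulate_gtt(p, beta_fixed, bolus=bolus, duration=duration)
            except (SteadyStateError, IntegrationError) as exc:
                raise SteadyStateError(
                    f"surface cell failed at Sbeta={s_b:g}, SP={s_p:g}: {exc}"
                ) from exc
            A[i, j] = augc(curve)
            B[i, j] = auic(curve)
    return AUGCSurface(sbeta_grid=sb, sp_grid=sp, augc=A, auic=B)


def _solve_sp_for_augc(
    augc_fn: Callable[[float, float], float],
    sbeta: float,
    target: float,
    sp_bracket: Tuple[float, float],
) -> float:
    """Solve AUGC(sbeta, sp) = target for sp by bracketed root finding."""
    lo, hi = sp_bracket
    f_lo = augc_fn(sbeta, lo) - target
    f_hi = augc_fn(sbeta, hi) - target
    if f_lo < 0 or f_hi > 0:
        # AUGC is decreasing in S_P, so attainable targets lie in
        # [AUGC(hi), AUGC(lo)].
        raise ValueError(
            f"target AUGC {target:g} outside attainable range "
            f"[{f_hi + target:g}, {f_lo + target:g}] at Sbeta={sbeta:g}"
        )
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    return float(brentq(lambda s: augc_fn(sbeta, s) - target, lo, hi, xtol=1e-12, rtol=1e-12))


def invert_sp(
    augc_fn: Callable[[float, float], float],
    augc_obs: Tuple[float, float],
    sbeta_band: Tuple[float, float],
    sp_bracket: Tuple[float, float],
) -> SPEstimate:
    """Invert an AUGC band and an Sβ band into an S_P interval.

    ``augc_fn(sbeta, sp)`` evaluates the forward map (typically a
    ``simulate_gtt`` + ``augc`` composition); ``augc_obs`` and
    ``sbeta_band`` are (mean, sem).  Because AUGC is increasing in Sβ
    and decreasing in S_P, the extreme compatible S_P values sit at
    opposite corners of the (Sβ, AUGC-target) rectangle: the interval is
    [solve(Sβ_lo, AUGC_hi), solve(Sβ_hi, AUGC_lo)].  Monotonicity in S_P
    is verified on the bracket.
    """
    a_mean, a_sem = augc_obs
    b_mean, b_sem = sbeta_band
    if a_sem < 0 or b_sem < 0:
        raise ValueError("sems must be >= 0")
    b_lo, b_hi = max(b_mean - b_sem, 0.0), b_mean + b_sem
    a_lo, a_hi = a_mean - a_sem, a_mean + a_sem
    lo_edge, hi_edge = sp_bracket
    if not (augc_fn(b_lo, lo_edge) > augc_fn(b_lo, hi_edge)):
        raise ValueError("AUGC is not decreasing in S_P over the bracket")
    sp_lo = _solve_sp_for_augc(augc_fn, b_lo, a_hi, sp_bracket)
    sp_hi = _solve_sp_for_augc(augc_fn, b_hi, a_lo, sp_bracket)
    if sp_lo > sp_hi:  # zero-width bands can invert the order by round-off
        sp_lo, sp_hi = sp_hi, sp_lo
    return SPEstimate(
        lo=sp_lo,
        hi=sp_hi,
        augc_mean=a_mean,
        augc_sem=a_sem,
        sbeta_mean=b_mean,
        sbeta_sem=b_sem,
    )


def gtt_augc_fn(
    template: ModelParams,
    beta_fixed: float,
    bolus: float = DEFAULT_BOLUS_MM,
    duration: float = DEFAULT_DURATION_MIN,
) -> Callable[[float, float], float]:
    """Forward map (Sβ, S_P) → AUGC by direct simulation (grid-free)."""

    def fn(sbeta: float, sp: float) -> float:
        p = template.replace(Sbeta=float(sbeta), SP=float(sp))
        return augc(simulate_gtt(p, beta_fixed, bolus=bolus, duration=duration))

    return fn
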