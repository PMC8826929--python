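"""Independent reference implementations used only as test oracles.

Everything here is deliberately written without importing the package's
own right-hand sides or solvers, so each check compares two genuinely
different code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp


def topp_rhs(y, R0, EG0, SI, sigma, alpha, k, d0, r1, r2):
    """Classical three-equation Topp model right-hand side.

    Algebra is arranged differently from the package (the Hill term is
    written as 1/(1 + alpha/G^2)) so agreement is not a tautology.
    """
    G, I, B = y
    dG = R0 - (EG0 + SI * I) * G
    hill = 1.0 / (1.0 + alpha / (G * G)) if G > 0 else 0.0
    dI = B * sigma * hill - k * I
    dB = B * (-d0 + r1 * G - r2 * G * G)
    return np.array([dG, dI, dB])


def topp_integrate(y0, t_grid, R0, EG0, SI, sigma, alpha, k, d0, r1, r2,
                   rtol=1e-12, atol=1e-14):
    """Integrate the classical Topp model with an independent solver call."""
    sol = solve_ivp(
        lambda t, y: topp_rhs(y, R0, EG0, SI, sigma, alpha, k, d0, r1, r2),
        (t_grid[0], t_grid[-1]),
        y0,
        method="LSODA",
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
    )
    assert sol.success, sol.message
    return sol.y


def modified_rhs(y, p, fast=False):
    """Hand-coded re-derivation of the feedback-model right-hand side."""
    G, I, B = y
    dG = p.R0 - p.EG0 * G - p.SP * I * G
    secretion = (B * p.sigma0 * G ** 2) / ((1.0 + p.Sbeta * I) * (p.alpha + G ** 2))
    dI = secretion - p.k * I
    dB = 0.0 if fast else B * (-p.d0 + p.r1 * G - p.r2 * G ** 2)
    return np.array([dG, dI, dB])


def rk4_integrate(rhs, y0, t_grid, substeps=20):
    """Fixed-step classical Runge–Kutta integrator."""
    y = np.array(y0, dtype=float)
    out = [y.copy()]
    for a, b in zip(t_grid[:-1], t_grid[1:]):
        h = (b - a) / substeps
        t = a
        for _ in range(substeps):
            k1 = rhs(y)
            k2 = rhs(y + 0.5 * h * k1)
            k3 = rhs(y + 0.5 * h * k2)
            k4 = rhs(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
        out.append(y.copy())
    return np.array(out).T


def clamp_insulin_bisection(p, G_clamp, beta, lo=0.0, hi=None, iters=200):
    """Bisection solve of beta*sigma0*Gf/(1+Sbeta*I) - k*I = 0."""
    Gf = G_clamp ** 2 / (p.alpha + G_clamp ** 2)

    def f(I):
        return beta * p.sigma0 * Gf / (1.0 + p.Sbeta * I) - p.k * I

    if hi is None:
        hi = max(1.0, 10.0 * beta * p.sigma0 * Gf / p.k)
        while f(hi) > 0:
            hi *= 2.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def fast_steady_state_grid(p, beta, g_max=None, levels=30, width_shrink=0.2, n=41):
    """2-D grid-refinement minimiser of the squared steady-state residual."""
    if g_max is None:
        g_max = p.R0 / p.EG0
    g_lo, g_hi = 1e-6, g_max
    i_lo, i_hi = 0.0, max(1.0, 10.0 * beta * p.sigma0 / p.k)

    def res2(G, I):
        dG = p.R0 - (p.EG0 + p.SP * I) * G
        dI = beta * p.sigma0 / (1 + p.Sbeta * I) * G * G / (p.alpha + G * G) - p.k * I
        return dG * dG + dI * dI

    for _ in range(levels):
        gs = np.linspace(g_lo, g_hi, n)
        is_ = np.linspace(i_lo, i_hi, n)
        GG, II = np.meshgrid(gs, is_, indexing="ij")
        R = res2(GG, II)
        i, j = np.unravel_index(np.argmin(R), R.shape)
        gw = (g_hi - g_lo) * width_shrink
        iw = (i_hi - i_lo) * width_shrink
        g_lo, g_hi = max(gs[i] - gw, 1e-9), gs[i] + gw
        i_lo, i_hi = max(is_[j] - iw, 0.0), is_[j] + iw
    return gs[i], is_[j]


def brute_force_peaks(values, baseline, threshold_pct):
    """Exhaustive local-maxima-then-threshold peak oracle.

    A peak is an interior sample strictly greater than the nearest
    differing value on each side; plateau runs count once at their
    leftmost sample.  Kept peaks exceed the percent-difference rule.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    peaks = []
    for i in range(1, n - 1):
        # leftmost sample of its plateau only
        if v[i] == v[i - 1]:
            continue
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 >= n:
            continue
        if v[i - 1] < v[i] and v[j + 1] < v[i]:
            if 100.0 * (v[i] - baseline) / baseline > threshold_pct:
                peaks.append(i)
    return np.array(peaks, dtype=int)


def naive_median(values):
    """Sort-and-pick-middle median."""
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])
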