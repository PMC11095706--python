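"""Tumor growth laws and the K-PD drug model.

Primary and secondary tumors follow the Gomp-Exp growth law

    g(v) = min(lambda * v, (alpha - beta * ln(v / V0)) * v),

an exponential rate cap ``lambda`` (the in vitro proliferation rate) grafted
onto a Gompertz law, which prevents the Gompertz rate from becoming
unrealistically fast at small sizes.  Sizes are carried internally in cells,
with ``V0 = 1`` cell and the conversion 1 mm^3 = 10^6 cells at the I/O
boundary.

Drug exposure uses a kinetics-pharmacodynamics (K-PD) shortcut: no measured
pharmacokinetics, the concentration after each oral dose simply decays
exponentially,

    C(t) = (1/Vd) * sum_i D_i * exp(-ke * (t - tau_i)) * 1{t > tau_i},

and treatment scales the unperturbed primary-tumor growth rate by
``(1 - k * C(t))`` (Norton-Simon hypothesis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "CELLS_PER_MM3",
    "GrowthParams",
    "KPDParams",
    "Schedule",
    "gomp_exp_rate",
    "growth_curve",
    "log_size_flow",
    "concentration",
    "concentration_integral",
    "effective_time",
    "solve_primary",
    "doubling_time",
]

#: conversion between caliper volume and cell number
CELLS_PER_MM3 = 1.0e6


@dataclass(frozen=True)
class GrowthParams:
    """Gomp-Exp growth constants for one tumor.

    Parameters
    ----------
    alpha, beta:
        Gompertz rate and decay constants (1/day).  The carrying capacity is
        ``V0 * exp(alpha / beta)``.
    lam:
        Exponential cap rate ``lambda`` (1/day), the in vitro proliferation
        rate.
    V0:
        Size of one cell; the unit of the size axis (default 1 cell).
    Vi:
        Implanted inoculum, size of the primary tumor at t=0
        (default 10^6 cells = 1 mm^3).
    """

    alpha: float
    beta: float
    lam: float
    V0: float = 1.0
    Vi: float = 1.0e6

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0 and self.lam > 0):
            raise ValueError("alpha, beta and lam must be positive")
        if not self.V0 > 0:
            raise ValueError("V0 must be positive")
        if not self.Vi >= self.V0:
            raise ValueError("Vi must be at least one cell (Vi >= V0)")

    @property
    def carrying_capacity(self) -> float:
        return self.V0 * np.exp(self.alpha / self.beta)

    @property
    def switch_log_size(self) -> float:
        """log(v/V0) at which the Gompertz rate equals the exponential cap."""
        return (self.alpha - self.lam) / self.beta


@dataclass(frozen=True)
class KPDParams:
    """K-PD constants: efficacy ``k`` (L/mg), elimination ``ke`` (1/day),
    volume of distribution ``Vd`` (L).  ``ke`` and ``Vd`` are literature
    constants, not estimated."""

    k: float
    ke: float = 3.26
    Vd: float = 12.0

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("drug efficacy k must be nonnegative")
        if not (self.ke > 0 and self.Vd > 0):
            raise ValueError("ke and Vd must be positive")


@dataclass(frozen=True)
class Schedule:
    """Neoadjuvant dosing schedule plus surgery.

    ``doses`` is a sequence of ``(amount mg/kg, day)`` pairs with strictly
    increasing administration days, all before ``resection_day``; the primary
    tumor is removed at ``resection_day`` and the simulation runs to
    ``horizon``.
    """

    doses: tuple[tuple[float, float], ...] = ()
    resection_day: float = 34.0
    horizon: float = 85.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "doses", tuple((float(d), float(t)) for d, t in self.doses))
        days = [t for _, t in self.doses]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("dose days must be strictly increasing")
        if days and days[-1] >= self.resection_day:
            raise ValueError("all doses must precede resection (neoadjuvant setting)")
        if not self.resection_day <= self.horizon:
            raise ValueError("resection_day must not exceed horizon")

    @property
    def dose_amounts(self) -> np.ndarray:
        return np.array([d for d, _ in self.doses], float)

    @property
    def dose_days(self) -> np.ndarray:
        return np.array([t for _, t in self.doses], float)


def gomp_exp_rate(v, p: GrowthParams):
    """Gomp-Exp growth rate g(v) = min(lam*v, (alpha - beta*ln(v/V0))*v).

    Negative only above the carrying capacity ``V0*exp(alpha/beta)``.
    """
    v = np.asarray(v, float)
    if np.any(v <= 0):
        raise ValueError("tumor size must be positive")
    gomp = (p.alpha - p.beta * np.log(v / p.V0)) * v
    out = np.minimum(p.lam * v, gomp)
    return out if out.ndim else float(out)


def log_size_flow(w0, phi, alpha, beta, lam):
    """Relative log-size ``w(phi) = ln(v/V0)`` after (possibly negative)
    effective time ``phi``, starting from ``w0``.

    Solves dw/dphi = min(lam, alpha - beta*w) in closed form.  The flow is
    autonomous, so negative ``phi`` traces the trajectory backwards; this is
    what makes the treated primary-tumor solution exact (see
    :func:`solve_primary`).  All arguments broadcast.
    """
    w0, phi, alpha, beta, lam = np.broadcast_arrays(
        *(np.asarray(a, float) for a in (w0, phi, alpha, beta, lam))
    )
    winf = alpha / beta            # log carrying capacity
    wstar = (alpha - lam) / beta   # exponential/Gompertz switch
    out = np.empty_like(phi)

    lo = w0 < wstar                # starts in the exponential phase
    # time (from w0) at which the Gompertz rate drops to lam
    with np.errstate(divide="ignore", invalid="ignore"):
        ps_lo = np.where(lo, (wstar - w0) / lam, 0.0)
        # backward switch time for starts in the Gompertz phase (<= 0);
        # never reached (-inf) when starting at or above carrying capacity
        ratio = (wstar - winf) / np.where(lo, -1.0, w0 - winf)
        ps_hi = np.where(
            lo, 0.0,
            np.where(w0 >= winf, -np.inf, -np.log(np.maximum(ratio, 1e-300)) / beta),
        )

    m = lo & (phi <= ps_lo)
    out[m] = w0[m] + lam[m] * phi[m]
    m = lo & (phi > ps_lo)
    out[m] = winf[m] + (wstar[m] - winf[m]) * np.exp(-beta[m] * (phi[m] - ps_lo[m]))
    hi = ~lo
    m = hi & (phi >= ps_hi)
    out[m] = winf[m] + (w0[m] - winf[m]) * np.exp(-beta[m] * phi[m])
    m = hi & (phi < ps_hi)
    out[m] = wstar[m] + lam[m] * (phi[m] - ps_hi[m])
    return out if out.ndim else float(out)


def growth_curve(s, p: GrowthParams):
    """Size (cells) reached from one cell (``V0``) after time ``s``.

    This is the growth kernel ``V(s)`` of a newly seeded metastasis.
    Closed-form piecewise solution of dV/ds = g(V), V(0) = V0.
    """
    s = np.asarray(s, float)
    if np.any(s < 0):
        raise ValueError("elapsed time must be nonnegative")
    out = p.V0 * np.exp(log_size_flow(0.0, s, p.alpha, p.beta, p.lam))
    return out if out.ndim else float(out)


def concentration(t, sched: Schedule, kpd: KPDParams):
    """K-PD drug concentration C(t) in mg/L; zero before the first dose."""
    t = np.asarray(t, float)
    c = np.zeros_like(t)
    for D, tau in sched.doses:
        dt = t - tau
        c += np.where(dt > 0, D * np.exp(-kpd.ke * np.clip(dt, 0, None)), 0.0) / kpd.Vd
    return c if c.ndim else float(c)


def concentration_integral(t, sched: Schedule, kpd: KPDParams):
    """Integral of C from 0 to t, in closed form."""
    t = np.asarray(t, float)
    s = np.zeros_like(t)
    for D, tau in sched.doses:
        dt = np.clip(t - tau, 0.0, None)
        s += D / (kpd.Vd * kpd.ke) * (1.0 - np.exp(-kpd.ke * dt))
    return s if s.ndim else float(s)


def effective_time(t, sched: Schedule, kpd: KPDParams):
    """Norton-Simon effective time Phi(t) = t - k * int_0^t C(s) ds.

    Treatment rescales the growth rate by (1 - k*C), so the treated log-size
    trajectory is the untreated one evaluated at Phi(t).  Phi decreases while
    k*C(t) > 1 (net shrinkage).
    """
    return np.asarray(t, float) - kpd.k * concentration_integral(t, sched, kpd)


def _solve_primary_ode(p, kpd, sched, grid, rtol=1e-8, atol=1e-10):
    """Adaptive-RK reference path: integrate dln(V)/dt piecewise between dose
    times (C(t) jumps at each administration)."""
    wstar = p.switch_log_size

    def rhs(t, w):
        rate = np.minimum(p.lam, p.alpha - p.beta * w)
        return rate * (1.0 - kpd.k * concentration(t, sched, kpd))

    t_end = min(sched.resection_day, grid[-1])
    breaks = np.concatenate([[grid[0]], sched.dose_days[sched.dose_days > grid[0]], [t_end]])
    breaks = np.unique(np.clip(breaks, grid[0], t_end))
    w = np.full(grid.shape, -np.inf)
    w0 = np.log(p.Vi / p.V0)
    for a, b in zip(breaks[:-1], breaks[1:]):
        if b <= a:
            continue
        sol = solve_ivp(rhs, (a, b), [w0], method="DOP853", rtol=rtol, atol=atol,
                        dense_output=True)
        if not sol.success:
            raise RuntimeError(f"primary-tumor ODE failed on [{a}, {b}]: {sol.message}")
        mask = (grid >= a) & (grid <= b) & (grid < sched.resection_day)
        if mask.any():
            w[mask] = sol.sol(grid[mask])[0]
        w0 = sol.y[0, -1]
    return np.where(grid < sched.resection_day, p.V0 * np.exp(w), 0.0)


def solve_primary(p: GrowthParams, kpd: KPDParams, sched: Schedule, grid,
                  method: str = "analytic") -> np.ndarray:
    """Primary-tumor trajectory (cells) on ``grid`` under the K-PD model.

    dVp/dt = g_p(Vp) * (1 - k*C(t)), Vp(0) = Vi, and Vp = 0 from
    ``resection_day`` on (surgical removal).

    The default path evaluates the exact warped-time solution
    ``Vp(t) = V0 * exp(w(Phi(t)))`` with ``Phi`` from
    :func:`effective_time`; ``method="ode"`` integrates the rate equation
    with an adaptive Runge-Kutta scheme restarted at every dose time, and is
    kept as an independent numerical cross-check.
    """
    grid = np.asarray(grid, float)
    if method == "ode":
        return _solve_primary_ode(p, kpd, sched, grid)
    if method != "analytic":
        raise ValueError(f"unknown method {method!r}")
    phi = effective_time(grid, sched, kpd)
    w = log_size_flow(np.log(p.Vi / p.V0), phi, p.alpha, p.beta, p.lam)
    return np.where(grid < sched.resection_day, p.V0 * np.exp(w), 0.0)


def doubling_time(alpha: float, beta: float, Vi: float = 1.0e6, V0: float = 1.0) -> float:
    """Gompertz doubling time (days) at size ``Vi``.

    DT = -(1/beta) * ln((ln 2 + A) / A) with A = ln(Vi/V0) - alpha/beta:
    the time for a pure-Gompertz tumor started at ``Vi`` to reach ``2*Vi``.
    Requires A < -ln 2 (doubling reachable below the carrying capacity).
    """
    A = np.log(Vi / V0) - alpha / beta
    if not A < -np.log(2.0):
        raise ValueError(
            "tumor cannot double: ln(Vi/V0) - alpha/beta must be below -ln(2)"
        )
    return float(-np.log1p(np.log(2.0) / A) / beta)
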