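"""Size-structured metastatic model and per-individual simulation.

Metastases are seeded from the primary tumor at the volume-dependent rate
``d(Vp) = mu * Vp`` and then grow independently with the untreated Gomp-Exp
law (treatment validated to act on the primary tumor only).  The density
``rho(t, v)`` of metastases of size ``v`` obeys a transport equation with
boundary influx ``d(Vp(t))``; the total metastatic burden reduces to the
convolution

    M(t) = int_0^t d(Vp(t - s)) * V(s) ds,

with ``V(s)`` the growth kernel of a single metastasis
(:func:`metanat.growth.growth_curve`).  On a uniform grid this is evaluated
by FFT with zero padding; an O(n^2) trapezoidal quadrature and an explicit
``rho`` evaluator along characteristics are kept as independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .growth import (CELLS_PER_MM3, GrowthParams, KPDParams, Schedule,
                     concentration, gomp_exp_rate, growth_curve, log_size_flow,
                     solve_primary)

__all__ = [
    "MetParams",
    "Trajectory",
    "dissemination_rate",
    "metastatic_burden_fft",
    "metastatic_burden_quadrature",
    "n_metastases",
    "simulate_individual",
    "simulate_scenario",
    "rho_density",
    "burden_from_density",
    "default_grid",
]


@dataclass(frozen=True)
class MetParams:
    """Dissemination coefficient ``mu``: daily per-cell probability that a
    primary-tumor cell establishes a distant metastasis (cell^-1 day^-1)."""

    mu: float

    def __post_init__(self) -> None:
        if self.mu < 0:
            raise ValueError("mu must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """One subject's simulated course.

    times (days), pt (primary tumor, cells; 0 after resection), conc (drug
    concentration, mg/L), mb (total metastatic burden, cells), n_mets
    (cumulative expected number of seeded metastases).
    """

    times: np.ndarray
    pt: np.ndarray
    conc: np.ndarray
    mb: np.ndarray
    n_mets: np.ndarray

    def to_frame(self, animal_id: str | int = 0) -> pd.DataFrame:
        """Tidy long-format export."""
        rows = {
            "pt_mm3": self.pt / CELLS_PER_MM3,
            "pt_cells": self.pt,
            "mb_cells": self.mb,
            "conc_mg_per_L": self.conc,
            "n_mets": self.n_mets,
        }
        frames = [
            pd.DataFrame({"animal_id": animal_id, "time_day": self.times,
                          "variable": name, "value": vals})
            for name, vals in rows.items()
        ]
        return pd.concat(frames, ignore_index=True)


def default_grid(horizon: float = 85.0, dt: float = 0.05) -> np.ndarray:
    """Uniform simulation grid over [0, horizon]."""
    n = int(round(horizon / dt))
    return np.linspace(0.0, n * dt, n + 1)


def _check_uniform(times: np.ndarray) -> float:
    steps = np.diff(times)
    if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-12):
        raise ValueError("time grid must be uniform")
    return float(steps[0])


def dissemination_rate(vp, m: MetParams):
    """Metastatic seeding rate d(Vp) = mu * Vp (new metastases per day)."""
    vp = np.asarray(vp, float)
    if np.any(vp < 0):
        raise ValueError("primary tumor size must be nonnegative")
    out = m.mu * vp
    return out if out.ndim else float(out)


def _jump_adjusted(pt: np.ndarray) -> np.ndarray:
    """Trapezoid-ready copy of a primary-tumor trajectory.

    Vp drops to 0 exactly at the resection node; integrating the jump with
    plain trapezoid weights loses half a cell there.  The second-order
    treatment replaces the node value by the mean of the one-sided limits,
    with the left limit linearly extrapolated from the last two live nodes.
    """
    pt = np.asarray(pt, float)
    if pt.ndim > 1:
        out = pt.copy()
        for r in range(pt.shape[0]):
            out[r] = _jump_adjusted(pt[r])
        return out
    live = pt > 0
    if live.all() or not live[0]:
        return pt
    j = int(np.argmin(live))  # first zero node (the resection instant)
    left = 2 * pt[j - 1] - pt[j - 2] if j >= 2 else pt[j - 1]
    out = pt.copy()
    out[j] = 0.5 * max(left, pt[j - 1])
    return out


def _fft_convolve_batch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Linear convolution of the trailing axes of ``a`` and ``b`` (equal
    length n), truncated to the first n lags.  Zero-pads to >= 2n-1 to avoid
    circular wrap-around."""
    n = a.shape[-1]
    size = sp_fft.next_fast_len(2 * n - 1)
    fa = sp_fft.rfft(a, size, axis=-1)
    fb = sp_fft.rfft(b, size, axis=-1)
    return sp_fft.irfft(fa * fb, size, axis=-1)[..., :n]


def _burden_trapezoid_fft(pt: np.ndarray, kernel: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoidal discretization of the burden convolution, via FFT."""
    conv = _fft_convolve_batch(pt, kernel) * dt
    corr = 0.5 * dt * (pt * kernel[..., :1] + pt[..., :1] * kernel)
    return np.maximum(conv - corr, 0.0)


def metastatic_burden_fft(pt_traj, g: GrowthParams, m: MetParams, times) -> np.ndarray:
    """Metastatic burden M(t) (cells) on a uniform grid, by FFT convolution
    of the seeding rate ``mu * Vp`` with the untreated growth kernel."""
    times = np.asarray(times, float)
    pt = np.asarray(pt_traj, float)
    dt = _check_uniform(times)
    kernel = growth_curve(times - times[0], g)
    return m.mu * _burden_trapezoid_fft(_jump_adjusted(pt), kernel, dt)


def metastatic_burden_quadrature(pt_traj, g: GrowthParams, m: MetParams, times) -> np.ndarray:
    """O(n^2) trapezoidal oracle for :func:`metastatic_burden_fft`."""
    times = np.asarray(times, float)
    pt = np.asarray(pt_traj, float)
    _check_uniform(times)
    kernel = growth_curve(times - times[0], g)
    ptj = _jump_adjusted(pt)
    out = np.zeros_like(times)
    for i in range(1, times.size):
        out[i] = np.trapezoid(ptj[: i + 1][::-1] * kernel[: i + 1], times[: i + 1])
    return m.mu * out


def n_metastases(pt_traj, m: MetParams, times) -> np.ndarray:
    """Cumulative expected metastasis count N(t) = int_0^t mu * Vp(u) du."""
    times = np.asarray(times, float)
    pt = _jump_adjusted(np.asarray(pt_traj, float))
    out = np.concatenate([[0.0], np.cumsum(0.5 * np.diff(times) * (pt[1:] + pt[:-1]))])
    return m.mu * out


def simulate_individual(g: GrowthParams, kpd: KPDParams, m: MetParams,
                        sched: Schedule, times=None) -> Trajectory:
    """Full forward simulation of one subject.

    The primary tumor follows the treated K-PD dynamics and is removed at
    resection; metastases grow with the *untreated* law (the validated
    scenario: treatment suppresses primary-tumor growth only) and seeding
    stops at surgery because Vp = 0.
    """
    if times is None:
        times = default_grid(sched.horizon)
    times = np.asarray(times, float)
    pt = solve_primary(g, kpd, sched, times)
    mb = metastatic_burden_fft(pt, g, m, times)
    return Trajectory(times=times, pt=pt, conc=np.asarray(concentration(times, sched, kpd)),
                      mb=mb, n_mets=n_metastases(pt, m, times))


def _simulate_batch(alpha, beta, k, mu, fixed: KPDParams, lam: float,
                    sched: Schedule, times, Vi: float = 1.0e6, V0: float = 1.0):
    """Vectorized forward simulation for a batch of parameter vectors.

    Returns (pt, mb) with shape (n, len(times)).  Shared schedule; per-subject
    (alpha, beta, k, mu).  Used by the population simulator and the SAEM
    fitter, where thousands of model evaluations are needed.
    """
    times = np.asarray(times, float)
    dt = _check_uniform(times)
    alpha, beta, k, mu = (np.atleast_1d(np.asarray(x, float)) for x in (alpha, beta, k, mu))
    n = alpha.size
    # effective time per subject: Phi_i(t) = t - k_i * int C
    from .growth import concentration_integral
    intc = np.asarray(concentration_integral(times, sched, fixed))
    phi = times[None, :] - k[:, None] * intc[None, :]
    w0 = np.log(Vi / V0)
    wp = log_size_flow(w0, phi, alpha[:, None], beta[:, None], lam)
    # cap at exp(345) so absurd MCMC proposals (and their convolution
    # products) stay finite and get rejected on likelihood, not on overflow
    pt = np.where(times[None, :] < sched.resection_day,
                  V0 * np.exp(np.minimum(wp, 345.0)), 0.0)
    kern = V0 * np.exp(np.minimum(log_size_flow(0.0, times[None, :] - times[0],
                                                alpha[:, None], beta[:, None], lam), 345.0))
    # second-order treatment of the resection jump (see _jump_adjusted)
    ptj = pt
    j = int(np.searchsorted(times, sched.resection_day))
    if j < times.size and np.all(pt[:, j] == 0.0) and j >= 2:
        ptj = pt.copy()
        ptj[:, j] = 0.5 * np.maximum(2 * pt[:, j - 1] - pt[:, j - 2], pt[:, j - 1])
    mb = mu[:, None] * _burden_trapezoid_fft(ptj, kern, dt)
    assert pt.shape == (n, times.size)
    return pt, mb


def _arrest_warp(elapsed_from, t, t_on, t_off):
    """Effective growth time between ``elapsed_from`` and ``t`` when growth
    is arrested during [t_on, t_off]."""
    overlap = np.clip(np.minimum(t, t_off) - np.maximum(elapsed_from, t_on), 0.0, None)
    return (t - elapsed_from) - overlap


def simulate_scenario(scenario: str, g: GrowthParams, m: MetParams,
                      nat_window: tuple[float, float], sched: Schedule,
                      times=None) -> Trajectory:
    """Heuristic growth-arrest model of neoadjuvant therapy (no K-PD).

    During the treatment window ``nat_window = (t_on, t_off)``:

    * ``"A"`` — growth arrest of both the primary tumor and every metastasis;
    * ``"B"`` — growth arrest of the primary tumor only;
    * ``"none"`` — untreated model.

    Dissemination ``mu * Vp`` continues throughout (the primary is held, not
    removed).  No parameter fitting is involved; this is the
    hypothesis-screening model.
    """
    if scenario not in {"A", "B", "none"}:
        raise ValueError("scenario must be 'A', 'B' or 'none'")
    t_on, t_off = map(float, nat_window)
    if scenario != "none" and not (t_on < t_off <= sched.resection_day):
        raise ValueError("need t_on < t_off <= resection_day")
    if times is None:
        times = default_grid(sched.horizon)
    times = np.asarray(times, float)
    dt = _check_uniform(times)

    # primary tumor: untreated flow in arrest-warped time (scenarios A and B)
    if scenario == "none":
        eff_t = times
    else:
        eff_t = times - _arrest_overlap(times, t_on, t_off)
    w = log_size_flow(np.log(g.Vi / g.V0), eff_t, g.alpha, g.beta, g.lam)
    pt = np.where(times < sched.resection_day, g.V0 * np.exp(w), 0.0)

    if scenario == "A":
        # metastasis growth arrested too: the kernel of a metastasis born at
        # time u, observed at t, is V evaluated at the warped elapsed time
        mb = np.zeros_like(times)
        for i in range(1, times.size):
            t = times[i]
            u = times[: i + 1]
            s_eff = _arrest_warp(u, t, t_on, t_off)
            kern = growth_curve(s_eff, g)
            mb[i] = m.mu * np.trapezoid(pt[: i + 1] * kern, u)
    else:
        mb = metastatic_burden_fft(pt, g, m, times)

    return Trajectory(times=times, pt=pt, conc=np.zeros_like(times), mb=mb,
                      n_mets=n_metastases(pt, m, times))


def _arrest_overlap(t, t_on, t_off):
    return np.clip(np.minimum(t, t_off) - t_on, 0.0, None)


def rho_density(t: float, v, pt_interp, g: GrowthParams, m: MetParams):
    """Explicit metastatic size density rho(t, v) along characteristics.

    A metastasis of size ``v`` at time ``t`` was born at ``t - S(v)`` where
    ``S(v)`` inverts the growth kernel; transport gives
    ``rho(t, v) = d(Vp(t - S(v))) / g(v)``.  ``pt_interp`` maps time to
    primary-tumor size.  Zero for v outside (V0, V(t)).  Test oracle only;
    production uses the convolution form.
    """
    v = np.asarray(v, float)
    # invert the kernel: S(v) = age of a metastasis of size v
    w = np.log(v / g.V0)
    wstar = g.switch_log_size
    winf = g.alpha / g.beta
    with np.errstate(divide="ignore", invalid="ignore"):
        age = np.where(
            w < wstar,
            w / g.lam,
            max(wstar, 0.0) / g.lam - np.log((winf - w) / (winf - max(wstar, 0.0))) / g.beta,
        )
    born = t - age
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(
            (born >= 0) & (v > g.V0) & (v < growth_curve(t, g)),
            m.mu * pt_interp(np.clip(born, 0.0, None)) / gomp_exp_rate(v, g),
            0.0,
        )
    return rho


def burden_from_density(t: float, pt_interp, g: GrowthParams, m: MetParams,
                        n_sizes: int = 4000) -> float:
    """MB at time ``t`` by integrating ``v * rho(t, v)`` over size — the
    conservation cross-check of the convolution solver, computed in
    log-size space."""
    vmax = growth_curve(t, g)
    if vmax <= g.V0 * (1 + 1e-12):
        return 0.0
    lv = np.linspace(np.log(g.V0) + 1e-9, np.log(vmax) - 1e-9, n_sizes)
    v = np.exp(lv)
    integrand = v * rho_density(t, v, pt_interp, g, m) * v  # extra v: dv = v dlv
    return float(np.trapezoid(integrand, lv))
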