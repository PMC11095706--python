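"""Population parameter model and virtual-cohort regimen exploration.

Individual parameters theta_i = (alpha_i, beta_i, k_i, mu_i) are log-normal:
ln(theta_i) = ln(theta_pop) + eta_i, eta_i ~ N(0, Omega), with theta_pop the
vector of population medians.  Fixed constants (lambda, ke, Vd) carry no
random effect.  The regimen explorer simulates virtual cohorts under a grid
of neoadjuvant durations and dose levels, starting treatment at primary
tumor detection (day 27 by default) and delaying surgery accordingly, and
converts the day-85 metastatic burden into a relapse probability against a
percentile threshold of the untreated control arm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import GrowthParams, KPDParams, Schedule
from .metastasis import MetParams, _simulate_batch, default_grid, simulate_individual
from .schedules import daily_schedule

__all__ = [
    "PARAM_NAMES",
    "PopulationModel",
    "RegimenResult",
    "default_population",
    "cv_to_omega",
    "omega_to_cv",
    "sample_individuals",
    "pt_percent_change",
    "relapse_analysis",
    "plot_regimen_curves",
]

#: order of the random-effect parameter vector
PARAM_NAMES = ("alpha", "beta", "k", "mu")

#: population medians estimated on the ortho-surgical LM2-4 sunitinib study
_REF_MEDIANS = {"alpha": 1.94, "beta": 0.0911, "k": 0.446, "mu": 2.12e-11}
#: coefficients of variation (%) of the same estimates, sd/median convention
_REF_CV_PCT = {"alpha": 18.1, "beta": 19.7, "k": 32.1, "mu": 1.48e3}
_REF_FIXED = {"lam": 0.837, "ke": 3.26, "Vd": 12.0}
_REF_SIGMA = 0.0391


@dataclass(frozen=True)
class PopulationModel:
    """Log-normal population distribution of the mechanistic parameters.

    theta_pop: medians of (alpha, beta, k, mu); omega: covariance of the
    log-parameters; sigma_err: proportional error on the log observations
    (dimensionless, e.g. 0.0391 = 3.91%); fixed: (lam, ke, Vd).
    """

    theta_pop: np.ndarray
    omega: np.ndarray
    sigma_err: float
    lam: float = _REF_FIXED["lam"]
    ke: float = _REF_FIXED["ke"]
    Vd: float = _REF_FIXED["Vd"]
    Vi: float = 1.0e6
    V0: float = 1.0

    def __post_init__(self) -> None:
        theta = np.asarray(self.theta_pop, float)
        omega = np.asarray(self.omega, float)
        object.__setattr__(self, "theta_pop", theta)
        object.__setattr__(self, "omega", omega)
        if theta.shape != (4,) or np.any(theta <= 0):
            raise ValueError("theta_pop must be 4 positive medians (alpha, beta, k, mu)")
        if omega.shape != (4, 4) or not np.allclose(omega, omega.T):
            raise ValueError("omega must be a symmetric 4x4 matrix")
        if np.linalg.eigvalsh(omega).min() < -1e-10 * max(1.0, np.trace(omega)):
            raise ValueError("omega must be positive semidefinite")
        if self.sigma_err < 0:
            raise ValueError("sigma_err must be nonnegative")

    def growth_params(self, alpha=None, beta=None) -> GrowthParams:
        return GrowthParams(alpha=self.theta_pop[0] if alpha is None else alpha,
                            beta=self.theta_pop[1] if beta is None else beta,
                            lam=self.lam, V0=self.V0, Vi=self.Vi)

    def kpd_params(self, k=None) -> KPDParams:
        return KPDParams(k=self.theta_pop[2] if k is None else k, ke=self.ke, Vd=self.Vd)

    def met_params(self, mu=None) -> MetParams:
        return MetParams(mu=self.theta_pop[3] if mu is None else mu)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.theta_pop))


def cv_to_omega(cv_percent) -> np.ndarray:
    """Diagonal log-covariance from per-parameter CVs in percent.

    The CV convention is sd/median.  For a log-normal with log-variance w2,
    sd/median = sqrt(exp(w2) * (exp(w2) - 1)), which inverts to
    w2 = ln((1 + sqrt(1 + 4 c^2)) / 2) with c = cv/100.
    """
    c = np.asarray(cv_percent, float) / 100.0
    if np.any(c < 0):
        raise ValueError("cv must be nonnegative")
    w2 = np.log((1.0 + np.sqrt(1.0 + 4.0 * c**2)) / 2.0)
    return np.diag(w2)


def omega_to_cv(omega: np.ndarray) -> np.ndarray:
    """Inverse of :func:`cv_to_omega` (diagonal only), in percent."""
    w2 = np.diag(np.asarray(omega, float))
    return 100.0 * np.sqrt(np.exp(w2) * np.expm1(w2))


#: reported correlation between individual alpha and beta estimates
_REF_CORR_ALPHA_BETA = 0.997


def default_population(sigma_err: float = _REF_SIGMA,
                       growth_correlation: float = _REF_CORR_ALPHA_BETA) -> PopulationModel:
    """Reference population for the mouse ortho-surgical neoadjuvant
    sunitinib model: published medians, Omega rebuilt from the published CVs.

    Most off-diagonal correlations were not published numerically and default
    to zero, but the near-perfect reported correlation between the individual
    growth parameters alpha and beta (r = 0.997) is kept: with independent
    alpha and beta the carrying capacity exp(alpha/beta) would span ~14
    orders of magnitude across the cohort, which the real population does
    not.  Pass ``growth_correlation=0`` for a fully diagonal Omega.
    """
    theta = np.array([_REF_MEDIANS[p] for p in PARAM_NAMES])
    omega = cv_to_omega([_REF_CV_PCT[p] for p in PARAM_NAMES])
    omega[0, 1] = omega[1, 0] = growth_correlation * np.sqrt(omega[0, 0] * omega[1, 1])
    return PopulationModel(theta_pop=theta, omega=omega, sigma_err=sigma_err)


def sample_individuals(pm: PopulationModel, n: int, seed=None) -> pd.DataFrame:
    """Draw ``n`` individual parameter vectors theta_i = theta_pop*exp(eta_i),
    eta_i ~ N(0, Omega).  Returns a DataFrame with columns alpha, beta, k, mu."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    eta = rng.multivariate_normal(np.zeros(4), pm.omega, size=n, method="eigh")
    theta = pm.theta_pop[None, :] * np.exp(eta)
    return pd.DataFrame(theta, columns=list(PARAM_NAMES))


def pt_percent_change(traj, window) -> float:
    """Percent change of primary-tumor size over ``window = (t_on, t_end)``,
    with the end read just before resection if it coincides with it."""
    t_on, t_end = map(float, window)
    times, pt = np.asarray(traj.times, float), np.asarray(traj.pt, float)
    if not (times[0] <= t_on <= t_end <= times[-1]):
        raise ValueError("window outside trajectory support")
    v_on = float(np.interp(t_on, times, pt))
    alive = pt > 0
    v_end = float(np.interp(t_end, times[alive], pt[alive])) if alive.any() else 0.0
    if v_on <= 0:
        raise ValueError("primary tumor size is zero at window start")
    return 100.0 * (v_end - v_on) / v_on


@dataclass(frozen=True)
class RegimenResult:
    """Population outcome of one (duration, dose) neoadjuvant regimen."""

    duration: float
    dose_level: float
    final_mb_median_individual: float
    pt_pct_change_median: float
    pt_pct_change_p10: float
    pt_pct_change_p90: float
    relapse_prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.relapse_prob <= 1.0:
            raise ValueError("relapse_prob must lie in [0, 1]")


def relapse_analysis(pm: PopulationModel, durations=None, dose_levels=(60.0, 120.0, 240.0),
                     n: int = 1000, seed=None, start_day: float = 27.0,
                     horizon: float = 85.0, percentile: float = 30.0,
                     dt: float = 0.05, first_passage: bool = False):
    """Virtual-population exploration of neoadjuvant duration and dose.

    Treatment starts at ``start_day`` (detection), daily dosing for
    ``duration`` days, surgery at ``start_day + duration``.  The relapse
    threshold is the given percentile of the control arm's (0-day NAT,
    surgery at ``start_day``) metastatic burden at ``horizon``; a virtual
    subject relapses when its MB at ``horizon`` reaches the threshold (or,
    with ``first_passage``, at any grid time up to the horizon — identical
    here because MB is nondecreasing, kept for the metastasis-free-survival
    reading).

    Returns ``(threshold_cells, DataFrame of RegimenResult rows)``.
    """
    if n < 10:
        raise ValueError("need at least 10 virtual subjects for the percentile")
    if durations is None:
        durations = np.arange(0, 19)
    times = default_grid(horizon, dt)
    theta = sample_individuals(pm, n, seed)

    def run(dose, duration):
        # per-subject k enters _simulate_batch directly; the KPDParams slot
        # only carries the fixed (ke, Vd)
        duration = int(round(duration))
        resection = start_day + duration
        if duration == 0:
            sched = Schedule(doses=(), resection_day=start_day, horizon=horizon)
        else:
            sched = daily_schedule(dose, start_day, duration, resection, horizon)
        pt, mb = _simulate_batch(
            theta["alpha"].to_numpy(), theta["beta"].to_numpy(),
            theta["k"].to_numpy(), theta["mu"].to_numpy(),
            KPDParams(k=0.0, ke=pm.ke, Vd=pm.Vd),
            pm.lam, sched, times, Vi=pm.Vi, V0=pm.V0)
        return sched, pt, mb

    results = []
    control_sched, control_pt, control_mb = run(0.0, 0)
    mb_final_control = control_mb[:, -1]
    threshold = float(np.percentile(mb_final_control, percentile))

    for dose in dose_levels:
        for duration in np.asarray(durations):
            sched, pt, mb = run(dose, duration) if duration > 0 else (
                control_sched, control_pt, control_mb)
            mb_final = mb[:, -1] if not first_passage else mb.max(axis=1)
            relapse = float(np.mean(mb_final >= threshold))
            # PT percent change over the treatment window, per subject; a
            # zero-length window (0-day NAT) is 0% by definition
            if duration == 0:
                pct = np.zeros(pt.shape[0])
            else:
                i_on = int(np.searchsorted(times, start_day))
                i_end = max(int(np.searchsorted(times, sched.resection_day, "left")) - 1,
                            i_on)
                pct = 100.0 * (pt[:, i_end] - pt[:, i_on]) / pt[:, i_on]
            # median individual, deterministic
            med = simulate_individual(pm.growth_params(), pm.kpd_params(), pm.met_params(),
                                      sched, times)
            results.append(RegimenResult(
                duration=float(duration), dose_level=float(dose),
                final_mb_median_individual=float(med.mb[-1]),
                pt_pct_change_median=float(np.median(pct)),
                pt_pct_change_p10=float(np.percentile(pct, 10)),
                pt_pct_change_p90=float(np.percentile(pct, 90)),
                relapse_prob=relapse))
    frame = pd.DataFrame([r.__dict__ for r in results])
    return threshold, frame


def plot_regimen_curves(frame: pd.DataFrame, ax=None):
    """Relapse probability and median PT change versus NAT duration, one
    curve per dose level."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(1, 2, figsize=(9, 3.5), constrained_layout=True)
    for dose, sub in frame.groupby("dose_level"):
        sub = sub.sort_values("duration")
        ax[0].plot(sub["duration"], sub["pt_pct_change_median"], marker="o",
                   label=f"{dose:g} mg/kg")
        ax[0].fill_between(sub["duration"], sub["pt_pct_change_p10"],
                           sub["pt_pct_change_p90"], alpha=0.2)
        ax[1].plot(sub["duration"], sub["relapse_prob"], marker="o",
                   label=f"{dose:g} mg/kg")
    ax[0].set_xlabel("NAT duration (days)")
    ax[0].set_ylabel("PT change at surgery (%)")
    ax[1].set_xlabel("NAT duration (days)")
    ax[1].set_ylabel("P(metastatic relapse)")
    ax[1].legend(frameon=False)
    return ax
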