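"""Virtual study-cohort generator.

Emulates the ortho-surgical neoadjuvant design end to end: treatment arms
with their dosing presets, log-normal individual parameters with full
covariance, caliper (primary tumor, mm^3) and bioluminescence (metastatic
burden, photons/s) sampling days, the log-proportional observation noise of
the calibration model, and a biomarker panel with a configurable correlation
structure that by default carries no information about the dissemination
parameter mu.  The ground-truth parameters are retained alongside the noisy
observations so that estimation code can be validated by round-trip
(generate -> fit -> compare) experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .growth import CELLS_PER_MM3, Schedule
from .metastasis import simulate_individual, default_grid
from .population import PARAM_NAMES, PopulationModel, sample_individuals
from .schedules import schedule_preset, preset_names

__all__ = [
    "Arm",
    "StudyDesign",
    "SyntheticCohort",
    "default_design",
    "generate_cohort",
    "generate_biomarkers",
    "BIOMARKER_COLUMNS",
    "default_biomarker_spec",
]

BIOMARKER_COLUMNS = ("ki67", "cd31", "ki67_cd31_pos", "ki67_cd31_neg",
                     "ctc", "gmdsc", "mmdsc")


@dataclass(frozen=True)
class Arm:
    """One treatment arm: a named schedule preset and its group size."""

    preset: str
    n: int
    surgery_day: float = 34.0

    def schedule(self, horizon: float = 85.0) -> Schedule:
        return schedule_preset(self.preset, self.surgery_day, horizon)


@dataclass(frozen=True)
class StudyDesign:
    """Measurement design of a virtual study.

    Caliper (PT) measurements run twice weekly from first palpability to
    surgery; BLI (MB) measurements run weekly from surgery to the horizon —
    a typical cadence for studies of this duration.  ``bli_conversion`` is
    the photons/s emitted per metastatic cell; the true instrument constant
    is not published, and nothing downstream depends on its value as long as
    generation and fitting share it.
    """

    arms: tuple[Arm, ...]
    horizon: float = 85.0
    pt_start_day: float = 14.0
    pt_every_days: float = 3.5
    mb_every_days: float = 7.0
    bli_conversion: float = 1.0

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("at least one arm required")
        for a in self.arms:
            if a.n < 1:
                raise ValueError("each arm needs n >= 1")
            if not 0 < a.surgery_day <= self.horizon:
                raise ValueError("surgery day must lie in (0, horizon]")

    def pt_sampling(self, surgery_day: float) -> np.ndarray:
        t = np.arange(self.pt_start_day, surgery_day, self.pt_every_days)
        return t

    def mb_sampling(self, surgery_day: float) -> np.ndarray:
        t = np.arange(surgery_day, self.horizon + 1e-9, self.mb_every_days)
        return t


def default_design(n_per_arm: int = 13, surgery_day: float = 34.0) -> StudyDesign:
    """The eight calibration arms (vehicle + seven sunitinib regimens) with
    equal group sizes; the default 13/arm yields 104 animals, the size of
    the calibration cohort."""
    arms = tuple(Arm(name, n_per_arm, surgery_day) for name in preset_names())
    return StudyDesign(arms=arms)


@dataclass
class SyntheticCohort:
    """Ground truth plus noisy observations for one simulated study."""

    truth: pd.DataFrame           # animal_id, arm, alpha, beta, k, mu
    observations: pd.DataFrame    # animal_id, time, observable(PT|MB), value
    schedules: dict               # animal_id -> Schedule
    design: StudyDesign
    population: PopulationModel
    seed: int | None
    biomarkers: pd.DataFrame | None = None

    def observations_for(self, animal_id) -> pd.DataFrame:
        return self.observations[self.observations["animal_id"] == animal_id]


def _noisy_log_obs(f_vals: np.ndarray, sigma: float, rng) -> np.ndarray:
    """Apply the calibration error model ln y = ln f * (1 + sigma*eps)."""
    lnf = np.log(f_vals)
    return np.exp(lnf * (1.0 + sigma * rng.standard_normal(lnf.shape)))


def generate_cohort(pm: PopulationModel, design: StudyDesign | None = None,
                    seed=None) -> SyntheticCohort:
    """Simulate a full virtual study.

    Each animal draws theta_i from the population, runs the K-PD forward
    model under its arm's schedule, and is observed with the log-proportional
    error model: PT in mm^3 before surgery, MB in photons/s from surgery on.
    Sampling times where the model prediction is so close to 1 (log ~ 0)
    that the error model degenerates are nudged later with a warning.
    """
    if design is None:
        design = default_design()
    rng = np.random.default_rng(seed)
    n_total = sum(a.n for a in design.arms)
    theta = sample_individuals(pm, n_total, rng)

    grid = default_grid(design.horizon, 0.05)
    rows, truth_rows, schedules = [], [], {}
    idx = 0
    for arm in design.arms:
        sched = arm.schedule(design.horizon)
        for _ in range(arm.n):
            aid = f"A{idx:03d}"
            th = theta.iloc[idx]
            traj = simulate_individual(
                pm.growth_params(th["alpha"], th["beta"]),
                pm.kpd_params(th["k"]), pm.met_params(th["mu"]),
                sched, grid)
            for observable, times, scale in (
                ("PT", design.pt_sampling(arm.surgery_day), 1.0 / CELLS_PER_MM3),
                ("MB", design.mb_sampling(arm.surgery_day), design.bli_conversion),
            ):
                series = traj.pt if observable == "PT" else traj.mb
                f = np.interp(times, grid, series) * scale
                bad = (f <= 0) | (np.abs(np.log(np.maximum(f, 1e-300))) < 0.05)
                tries = 0
                while bad.any() and tries < 20:
                    times = np.where(bad, times + 0.5, times)
                    f = np.interp(times, grid, series) * scale
                    bad = (f <= 0) | (np.abs(np.log(np.maximum(f, 1e-300))) < 0.05)
                    tries += 1
                if bad.any():
                    warnings.warn(f"dropping {bad.sum()} degenerate {observable} "
                                  f"sampling points for {aid}")
                    times, f = times[~bad], f[~bad]
                y = _noisy_log_obs(f, pm.sigma_err, rng)
                rows.append(pd.DataFrame({"animal_id": aid, "time": times,
                                          "observable": observable, "value": y}))
            truth_rows.append({"animal_id": aid, "arm": arm.preset,
                               "surgery_day": arm.surgery_day,
                               **{p: th[p] for p in PARAM_NAMES}})
            schedules[aid] = sched
            idx += 1
    obs = pd.concat(rows, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return SyntheticCohort(truth=truth, observations=obs, schedules=schedules,
                           design=design, population=pm,
                           seed=seed if isinstance(seed, int) else None)


# --- biomarker panel ---------------------------------------------------------

#: marginal distributions: (kind, loc/median, scale/log-sd)
_BIOMARKER_MARGINALS = {
    "ki67": ("normal_pct", 30.0, 8.0),            # % positive cells
    "cd31": ("normal_pct", 5.0, 1.5),             # % area
    "ki67_cd31_pos": ("lognormal", 6.0, 0.6),     # proliferating endothelial count
    "ki67_cd31_neg": ("normal_count", 300.0, 90.0),  # tracks Ki67 almost linearly
    "ctc": ("lognormal", 50.0, 0.8),              # cells per blood volume
    "gmdsc": ("lognormal", 2000.0, 0.6),
    "mmdsc": ("lognormal", 500.0, 0.6),
}


def _latent_correlation(r: float, kind_i: str, s_i: float, kind_j: str,
                        s_j: float) -> float:
    """Latent Gaussian correlation that reproduces an observed-scale Pearson
    ``r`` after the marginal transforms (moment matching; clipping of the
    normal marginals is ignored as negligible)."""
    if r == 0.0:
        return 0.0
    log_i, log_j = kind_i == "lognormal", kind_j == "lognormal"
    if not log_i and not log_j:
        return r
    if log_i and log_j:
        arg = 1.0 + r * np.sqrt(np.expm1(s_i**2) * np.expm1(s_j**2))
        if arg <= 0:
            raise ValueError(f"target correlation {r} infeasible for the "
                             "given log-normal marginals")
        return np.log(arg) / (s_i * s_j)
    s = s_i if log_i else s_j
    rho = r * np.sqrt(np.expm1(s**2)) / s
    if abs(rho) > 1.0:
        warnings.warn(f"target correlation {r} not attainable through a "
                      f"log-normal marginal (log-sd {s}); clamping")
        rho = np.sign(rho)
    return rho


def default_biomarker_spec() -> pd.DataFrame:
    """Default biomarker correlation matrix: identity except the two strong
    empirical redundancies — Ki67 with Ki67+/CD31- (r = 0.979) and CTC with
    gMDSC (r = 0.678)."""
    cols = list(BIOMARKER_COLUMNS)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    r.loc["ki67", "ki67_cd31_neg"] = r.loc["ki67_cd31_neg", "ki67"] = 0.979
    r.loc["ctc", "gmdsc"] = r.loc["gmdsc", "ctc"] = 0.678
    return r


def _nearest_psd(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= 0:
        return mat
    warnings.warn("correlation target not PSD; projecting to nearest PSD matrix")
    vals = np.clip(vals, 1e-10, None)
    out = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    return out / np.outer(d, d)


def generate_biomarkers(cohort: SyntheticCohort, correlation_spec: pd.DataFrame | None = None,
                        mu_association: float = 0.0, assoc_marker: str = "ctc",
                        seed=None) -> pd.DataFrame:
    """Per-animal biomarker panel via a Gaussian copula.

    ``correlation_spec`` holds target Pearson correlations on the observed
    biomarker scale (defaults embed the two strong empirical marker
    redundancies); the latent Gaussian correlations are moment-matched so
    the targets survive the marginal transforms.  ``mu_association`` is the
    R^2 of an optional linear association between ``assoc_marker``'s latent
    score and ln(mu_i); the default 0 reflects the study finding that no
    measured biomarker tracked dissemination.  The table is attached to the
    cohort and returned.
    """
    if correlation_spec is None:
        correlation_spec = default_biomarker_spec()
    cols = list(correlation_spec.columns)
    target = correlation_spec.to_numpy(float)
    if np.any(np.abs(target - np.diag(np.diag(target))) >= 1.0):
        raise ValueError("target correlations must have |r| < 1")
    # correlation targets are on the observed biomarker scale; derive the
    # latent Gaussian correlations that reproduce them after the marginals
    latent = np.eye(len(cols))
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            ki, ai, bi = _BIOMARKER_MARGINALS[cols[i]]
            kj, aj, bj = _BIOMARKER_MARGINALS[cols[j]]
            latent[i, j] = latent[j, i] = _latent_correlation(
                target[i, j], ki, bi, kj, bj)
    corr = _nearest_psd(latent)
    if not 0.0 <= mu_association < 1.0:
        raise ValueError("mu_association is an R^2 in [0, 1)")
    rng = np.random.default_rng(seed)
    n = len(cohort.truth)
    z = rng.multivariate_normal(np.zeros(len(cols)), corr, size=n, method="eigh")

    if mu_association > 0:
        lnmu = np.log(cohort.truth["mu"].to_numpy())
        zmu = (lnmu - lnmu.mean()) / max(lnmu.std(), 1e-12)
        j = cols.index(assoc_marker)
        z[:, j] = np.sqrt(mu_association) * zmu + np.sqrt(1 - mu_association) * z[:, j]

    out = {"animal_id": cohort.truth["animal_id"].to_numpy()}
    for j, name in enumerate(cols):
        kind, a, b = _BIOMARKER_MARGINALS[name]
        if kind == "normal_pct":
            out[name] = np.clip(a + b * z[:, j], 0.0, 100.0)
        elif kind == "normal_count":
            out[name] = np.clip(a + b * z[:, j], 0.0, None)
        else:  # lognormal with median a and log-sd b
            out[name] = a * np.exp(b * z[:, j])
    table = pd.DataFrame(out)
    cohort.biomarkers = table
    return table
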