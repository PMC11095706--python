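"""Mixed-effects estimation: likelihood, SAEM, EBEs, diagnostics, SEs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from metanat.cohort import Arm, StudyDesign, generate_cohort
from metanat.nlme import (CohortData, ModelEvaluationError, SAEMSettings,
                          diagnostics, ebe_estimate, loglik_individual,
                          rse_estimate, saem_fit)
from metanat.population import PARAM_NAMES, PopulationModel, default_population

QUICK = SAEMSettings(n_explore=60, n_smooth=40, n_transitions=2, grid_dt=0.1)


@pytest.fixture(scope="module")
def cohort24(pm_default):
    design = StudyDesign(arms=(Arm("vehicle", 8), Arm("Su60(14D)", 8),
                               Arm("Su120(3D)+Su60(11D)", 8)))
    return generate_cohort(pm_default, design, seed=2024)


@pytest.fixture(scope="module")
def theta_median(pm_default):
    return dict(zip(PARAM_NAMES, pm_default.theta_pop))


class TestLoglikIndividual:
    def test_exact_prediction_sits_at_the_mode(self, pm_default, cohort24,
                                               theta_median):
        aid = cohort24.truth["animal_id"].iloc[0]
        obs = cohort24.observations_for(aid).copy()
        obs = obs.sort_values(["animal_id", "observable", "time"]).reset_index(drop=True)
        sched = cohort24.schedules[aid]
        th = cohort24.truth.set_index("animal_id").loc[aid, list(PARAM_NAMES)].to_dict()
        # replace observations by the animal's own noiseless predictions
        data = CohortData.from_frames(
            obs.assign(animal_id="x"), {"x": sched}, pm_default, 0.05)
        lnf = data.predict_ln_f(np.log([[th[p] for p in PARAM_NAMES]]))
        obs_exact = obs.assign(value=np.exp(lnf))
        ll = loglik_individual(th, obs_exact, sched, pm_default.sigma_err, pm_default)
        mode = np.sum(-0.5 * np.log(2 * np.pi)
                      - np.log(pm_default.sigma_err * np.abs(lnf)))
        assert ll == pytest.approx(mode, rel=1e-9)
        # any perturbation of the data lowers the density
        obs_pert = obs_exact.assign(value=obs_exact["value"] * 1.05)
        assert loglik_individual(th, obs_pert, sched, pm_default.sigma_err,
                                 pm_default) < ll

    def test_vanishing_noise_rejects_mismatched_data(self, pm_default, cohort24,
                                                     theta_median):
        aid = cohort24.truth["animal_id"].iloc[0]
        obs = cohort24.observations_for(aid)
        sched = cohort24.schedules[aid]
        ll_small = loglik_individual(theta_median, obs, sched, 1e-6, pm_default)
        ll_ref = loglik_individual(theta_median, obs, sched, 0.04, pm_default)
        assert ll_small < ll_ref - 1e4

    def test_profile_likelihood_peaks_at_true_sigma(self, pm_default):
        dense = StudyDesign(arms=(Arm("vehicle", 1),), pt_every_days=1.0,
                            mb_every_days=2.0)
        pm = dataclasses.replace(pm_default, omega=np.zeros((4, 4)))
        co = generate_cohort(pm, dense, seed=11)
        aid = co.truth["animal_id"].iloc[0]
        obs, sched = co.observations_for(aid), co.schedules[aid]
        th = dict(zip(PARAM_NAMES, pm.theta_pop))
        grid = [0.015, 0.025, 0.0391, 0.06, 0.1]
        lls = [loglik_individual(th, obs, sched, s, pm) for s in grid]
        assert int(np.argmax(lls)) == 2

    def test_degenerate_error_model_is_reported(self, pm_default, control_schedule):
        # the inoculum is exactly 1 mm^3, so a PT observation at t=0 has
        # ln f = 0 and the log-proportional variance vanishes
        obs = pd.DataFrame({"animal_id": ["x"], "time": [0.0],
                            "observable": ["PT"], "value": [1.0001]})
        th = dict(zip(PARAM_NAMES, pm_default.theta_pop))
        with pytest.raises(ModelEvaluationError):
            loglik_individual(th, obs, control_schedule, 0.04, pm_default)


class TestSaemFit:
    def test_deterministic_under_fixed_seed(self, pm_default, cohort24):
        sub = cohort24.truth["animal_id"].iloc[:10]
        obs = cohort24.observations[cohort24.observations.animal_id.isin(sub)]
        sch = {a: cohort24.schedules[a] for a in sub}
        tiny = SAEMSettings(n_explore=25, n_smooth=15, n_transitions=1, grid_dt=0.1)
        f1 = saem_fit(obs, sch, pm_default, tiny, seed=5)
        f2 = saem_fit(obs, sch, pm_default, tiny, seed=5)
        assert np.array_equal(f1.theta_pop, f2.theta_pop)
        assert f1.sigma_err == f2.sigma_err

    def test_noiseless_homogeneous_cohort_collapses_to_least_squares(self, pm_default):
        degen = PopulationModel(theta_pop=pm_default.theta_pop,
                                omega=np.zeros((4, 4)), sigma_err=0.0)
        co = generate_cohort(degen, StudyDesign(arms=(Arm("vehicle", 4),
                                                      Arm("Su60(14D)", 4))), seed=3)
        init = dataclasses.replace(
            degen, theta_pop=degen.theta_pop * np.array([1.3, 0.8, 1.4, 3.0]),
            omega=0.04 * np.eye(4), sigma_err=0.05)
        fit = saem_fit(co.observations, co.schedules, init,
                       SAEMSettings(n_explore=120, n_smooth=80, n_transitions=3,
                                    grid_dt=0.1), seed=8)
        assert fit.theta_pop == pytest.approx(pm_default.theta_pop, rel=0.01)
        assert fit.sigma_err < 0.01

    def test_recovery_on_heterogeneous_cohort(self, pm_default, cohort24):
        init = dataclasses.replace(
            pm_default, theta_pop=pm_default.theta_pop * np.array([1.3, 0.75, 1.5, 10.0]),
            sigma_err=0.08)
        fit = saem_fit(cohort24.observations, cohort24.schedules, init,
                       SAEMSettings(n_explore=120, n_smooth=80, n_transitions=3,
                                    grid_dt=0.1), seed=13)
        ratio = fit.theta_pop / pm_default.theta_pop
        assert ratio[0] == pytest.approx(1.0, abs=0.10)   # alpha
        assert ratio[1] == pytest.approx(1.0, abs=0.10)   # beta
        assert ratio[2] == pytest.approx(1.0, abs=0.40)   # k (24 animals only)
        assert 1 / 5 < ratio[3] < 5                        # mu, CV ~ 1.5e3 %
        assert fit.sigma_err == pytest.approx(pm_default.sigma_err, rel=0.5)
        # exploration ends with stabilized smoothing: the averaged trace moves
        # far less in the second half of smoothing than during exploration
        tr = fit.trace["theta_alpha"].to_numpy()
        explore_move = np.abs(np.diff(tr[:120])).mean()
        smooth_move = np.abs(np.diff(tr[-40:])).mean()
        assert smooth_move < 0.2 * explore_move

    def test_refuses_single_animal(self, pm_default, cohort24):
        aid = cohort24.truth["animal_id"].iloc[0]
        obs = cohort24.observations_for(aid)
        with pytest.raises(ValueError):
            saem_fit(obs, {aid: cohort24.schedules[aid]}, pm_default, QUICK, seed=1)


class TestEbe:
    def test_tight_prior_pins_individuals_to_the_median(self, pm_default, cohort24):
        pm = dataclasses.replace(pm_default, omega=1e-8 * np.eye(4))
        sub = cohort24.truth["animal_id"].iloc[:4]
        obs = cohort24.observations[cohort24.observations.animal_id.isin(sub)]
        sch = {a: cohort24.schedules[a] for a in sub}
        ebe = ebe_estimate(pm, obs, sch)
        for p, v in zip(PARAM_NAMES, pm.theta_pop):
            assert ebe[p].to_numpy() == pytest.approx(v, rel=0.01)

    def test_rich_low_noise_data_recovers_individual_truth(self, pm_default):
        dense = StudyDesign(arms=(Arm("Su60(14D)", 3),), pt_every_days=1.0,
                            mb_every_days=2.0)
        pm = dataclasses.replace(pm_default, sigma_err=0.003)
        co = generate_cohort(pm, dense, seed=21)
        ebe = ebe_estimate(pm, co.observations, co.schedules, grid_dt=0.05)
        truth = co.truth.set_index("animal_id")
        for aid in truth.index:
            for p in ("alpha", "beta", "mu"):
                assert ebe.loc[aid, p] == pytest.approx(truth.loc[aid, p], rel=0.05)

    def test_animal_without_observations_returns_population_mode(self, pm_default,
                                                                 cohort24):
        aid = cohort24.truth["animal_id"].iloc[0]
        obs = cohort24.observations_for(aid).iloc[0:0]  # empty frame
        ebe = ebe_estimate(pm_default, obs, {aid: cohort24.schedules[aid]})
        assert ebe.loc[aid, list(PARAM_NAMES)].to_numpy() == \
            pytest.approx(pm_default.theta_pop, rel=1e-3)


@pytest.fixture(scope="module")
def diag(pm_default, cohort24):
    return diagnostics(pm_default, cohort24.observations, cohort24.schedules,
                       n_vpc_rep=100, seed=17)


class TestDiagnostics:
    def test_vpc_bands_cover_self_simulated_data(self, pm_default, cohort24, diag):
        # ~80% of observations should fall inside the simulated 10-90% band
        lo = diag.vpc[diag.vpc.percentile == 10].set_index(["observable", "time"])
        hi = diag.vpc[diag.vpc.percentile == 90].set_index(["observable", "time"])
        obs = cohort24.observations
        data = CohortData.from_frames(obs, cohort24.schedules, pm_default, 0.1)
        key = pd.DataFrame({
            "observable": np.where(data.obs_is_mb, "MB", "PT"),
            "time": (data.grid[data.obs_i0] + data.obs_frac *
                     (data.grid[data.obs_i0 + 1] - data.grid[data.obs_i0])).round(6),
            "ln_y": data.ln_y})
        merged = key.join(lo["sim_median"].rename("lo"), on=["observable", "time"]) \
                    .join(hi["sim_median"].rename("hi"), on=["observable", "time"])
        frac = np.mean((merged.ln_y >= merged.lo) & (merged.ln_y <= merged.hi))
        assert 0.68 <= frac <= 0.92

    def test_observed_percentiles_inside_prediction_bands(self, diag):
        ok = (diag.vpc.observed >= diag.vpc.sim_lo) & \
             (diag.vpc.observed <= diag.vpc.sim_hi)
        assert ok.mean() >= 0.8

    def test_iwres_standardized_for_consistent_model(self, diag):
        assert abs(diag.iwres["iwres"].mean()) < 0.2
        assert diag.iwres["iwres"].std() == pytest.approx(1.0, abs=0.3)

    def test_iwres_zero_for_noiseless_self_simulation(self, pm_default):
        degen = PopulationModel(theta_pop=pm_default.theta_pop,
                                omega=np.zeros((4, 4)), sigma_err=0.0)
        co = generate_cohort(degen, StudyDesign(arms=(Arm("vehicle", 3),)), seed=9)
        pm_eval = dataclasses.replace(degen, sigma_err=0.04)
        d = diagnostics(pm_eval, co.observations, co.schedules, n_vpc_rep=5, seed=1)
        assert np.max(np.abs(d.iwres["iwres"])) < 0.05

    def test_shrinkage_undefined_without_random_effect(self, pm_default, cohort24):
        pm = dataclasses.replace(pm_default, omega=np.diag([0.03, 0.04, 0.0, 2.7]))
        sub = cohort24.truth["animal_id"].iloc[:4]
        obs = cohort24.observations[cohort24.observations.animal_id.isin(sub)]
        sch = {a: cohort24.schedules[a] for a in sub}
        d = diagnostics(pm, obs, sch, n_vpc_rep=5, seed=2)
        assert np.isnan(d.shrinkage["k"])
        assert np.isfinite(d.shrinkage["alpha"])


class TestRse:
    def test_refuses_underpowered_bootstrap(self, pm_default, cohort24):
        fit = _dummy_fit(pm_default)
        with pytest.raises(ValueError):
            rse_estimate(cohort24.observations, cohort24.schedules, fit, B=5)

    def test_bootstrap_rse_positive_and_finite(self, pm_default, cohort24):
        sub = cohort24.truth["animal_id"].iloc[:8]
        obs = cohort24.observations[cohort24.observations.animal_id.isin(sub)]
        sch = {a: cohort24.schedules[a] for a in sub}
        fit = saem_fit(obs, sch, pm_default,
                       SAEMSettings(n_explore=25, n_smooth=15, n_transitions=1,
                                    grid_dt=0.1), seed=3)
        rse = rse_estimate(obs, sch, fit, method="bootstrap", B=20, seed=4,
                           settings=SAEMSettings(n_explore=15, n_smooth=10,
                                                 n_transitions=1, grid_dt=0.1))
        assert (rse >= 0).all() and np.isfinite(rse).all()
        # mu is by far the most uncertain parameter
        assert rse["mu"] > rse["alpha"]


    def test_fisher_sandwich_runs_on_tiny_cohort(self, pm_default, cohort24):
        sub = cohort24.truth["animal_id"].iloc[:4]
        obs = cohort24.observations[cohort24.observations.animal_id.isin(sub)]
        sch = {a: cohort24.schedules[a] for a in sub}
        fit = _dummy_fit(pm_default)
        rse = rse_estimate(obs, sch, fit, method="fisher", seed=2)
        assert (rse >= 0).all() and np.isfinite(rse).all()


def _dummy_fit(pm):
    from metanat.nlme import FitResult
    return FitResult(theta_pop=pm.theta_pop, omega=pm.omega,
                     sigma_err=pm.sigma_err, trace=pd.DataFrame(),
                     accept_rate=0.3, settings=SAEMSettings(), n_animals=10)
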