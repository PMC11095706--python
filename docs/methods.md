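# Methods

`metanat` models spontaneous metastasis in an ortho-surgical mouse model of
triple-negative breast cancer (LM2-4^LUC+^ cells implanted in the mammary fat
pad, resected after a neoadjuvant sunitinib window, metastatic burden followed
by bioluminescence), and the statistical machinery the analysis of such a
study needs: mixed-effects calibration, virtual-population simulation and a
biomarker regression benchmark. This note records the model, the numerical
choices, and what the synthetic data do and do not establish.

## Growth model

Primary tumor and metastases grow by the Gomp-Exp law

```
g(v) = min( lam * v, (alpha - beta * ln(v / V0)) * v )
```

with `V0` = 1 cell. The Gompertz term alone grows unrealistically fast at
small `v`; the cap `lam` (day^-1) is the in vitro proliferation rate. All
internal sizes are in cells; caliper volumes convert at 1 mm^3 = 10^6 cells,
so the inoculum `Vi` = 10^6 cells = 1 mm^3. Because the Gompertz log term is
scale-invariant, `(alpha, beta)` are unchanged by this unit choice.

Reference constants (population medians of the calibration study):
`alpha` = 1.94 /day, `beta` = 0.0911 /day, `lam` = 0.837 /day (fixed),
`k` = 0.446 L/mg, `ke` = 3.26 /day (fixed), `Vd` = 12 L (fixed),
`mu` = 2.12e-11 /cell/day, proportional error `sigma` = 3.91%.
`Vd` = 12 L is dimensionally odd for a mouse; it is a literature constant of
the K-PD parameterization and is used as a plain number, exactly as fixed in
the calibration.

## Treatment (K-PD, Norton–Simon)

No pharmacokinetic samples exist, so drug exposure is the postulated
kinetics-pharmacodynamics form: each oral dose `D_i` at day `tau_i` adds
`(D_i/Vd) * exp(-ke (t - tau_i))` for `t > tau_i` to the concentration
`C(t)`. Doses enter as the printed mg/kg numbers; no body-weight scaling is
applied because none is defined in the calibration. Treatment multiplies the
primary tumor's growth rate by `(1 - k C(t))` (Norton–Simon: the whole
`min(...)` rate is scaled); metastases grow *untreated*, the hypothesis the
scenario comparison (below) validates. `k C > 1` means net shrinkage.

### Exact solution by time warping

Writing `w = ln(Vp/V0)`, the treated equation is
`dw/dt = min(lam, alpha - beta w) * (1 - k C(t))`. The right-hand side
factorizes into an autonomous part and a time reparameterization, so
`w(t) = W(Phi(t))` where `W` is the untreated log-size flow (piecewise
closed form: exponential until `w* = (alpha - lam)/beta`, Gompertz beyond)
and `Phi(t) = t - k ∫_0^t C` is an "effective growth time", also closed
form. `Phi` runs backwards while `k C > 1`; the autonomous flow is simply
retraced. This is exact — no step-size error, no special handling of the
concentration jumps at dose times — and evaluates in microseconds, which is
what makes the SAEM chains and 1000-subject populations cheap. An adaptive
Runge–Kutta integration (DOP853, rtol 1e-8 / atol 1e-10 on `w`, restarted at
every dose time) is retained behind `method="ode"` purely as an independent
numerical cross-check; tests hold the two within 1e-4 on treated runs and
1e-6 on untreated ones.

## Metastasis model

Cells leave the primary at rate `d(Vp) = mu * Vp` and found metastases that
grow from one cell by the untreated law. The size density `rho(t, v)` obeys
the standard transport equation with boundary influx `d(Vp(t))`; total
burden reduces to the convolution `M(t) = ∫_0^t d(Vp(t-s)) V(s) ds` with
`V(s)` the single-metastasis growth kernel. Secondary seeding (metastases
seeding metastases) is excluded — the boundary term uses `Vp` only.

Numerics: uniform grid, default `dt` = 0.05 day; trapezoidal weights;
FFT with zero padding to `next_fast_len(2n-1)` to avoid circular
wrap-around. `Vp` drops to zero at the resection node; plain trapezoid
integration of a jump located on a node loses half a cell, so the node value
is replaced by the mean of the one-sided limits (left limit linearly
extrapolated), restoring second-order accuracy. Two independent oracles
guard the solver: an O(n^2) trapezoidal quadrature (agreement < 0.1% at
dt = 0.05) and an explicit `rho(t, v)` evaluated along characteristics and
integrated in log-size space (conservation check). `M` is exactly linear in
`mu` because `mu` enters only through the boundary term.

The day-85 burden is used as the "long-term" endpoint throughout, matching
the calibration study's horizon.

## Growth-arrest scenarios

The hypothesis screen runs without any fitting: during the treatment window,
scenario **A** freezes both primary and metastatic growth, scenario **B**
freezes the primary only (this follows the labeling of the study's figures
and results; its methods section swaps the letters — the figure/results
convention is used here). Arrest is implemented as the same time-warp idea:
the arrested clock simply stops, so a metastasis born at `u` has size
`V((t-u) - overlap([u,t], window))` under A. Dissemination `mu Vp`
continues during arrest. The orderings `MB_A <= MB_B <= MB_untreated` hold
pointwise and are tested.

## Population model and calibration

Individual parameters `theta_i = (alpha, beta, k, mu)` are log-normal:
`ln theta_i = ln theta_pop + eta_i`, `eta_i ~ N(0, Omega)` with full
covariance; `(lam, ke, Vd)` carry no random effects. Observations are
log-transformed with the calibration study's proportional error model

```
ln y = ln f(t; theta_i) * (1 + sigma * eps),   eps ~ N(0, 1),
```

i.e. the noise multiplies the *log* prediction — unusual, but implemented
literally (standard deviation `sigma * |ln f|`); a conventional proportional
error on `y` is available via `error_model="proportional_y"` for robustness
studies and is not used anywhere else. The model degenerates where
`ln f = 0` (prediction exactly 1 unit); such points raise an explicit error,
and the cohort generator nudges sampling times off the singularity.

**Default Omega.** The published table gives only per-parameter CVs
(sd/median; the log-variance solves
`cv^2 = exp(w2)(exp(w2)-1)`, i.e. `w2 = ln((1+sqrt(1+4 cv^2))/2)`). Its
off-diagonals were published only graphically, with one exception: the
individual `alpha` and `beta` estimates are reported as correlated at
r = 0.997. That correlation is structural — with independent `alpha` and
`beta` at their published CVs, the carrying capacity `exp(alpha/beta)` would
span ~14 orders of magnitude across a cohort, which the real animals do not
show, and the control-population burden distribution becomes so wide that
its lower percentiles are meaningless. The default population therefore
uses the diagonal CVs plus that single published correlation
(`growth_correlation=0` restores a fully diagonal Omega).

**SAEM.** Maximum likelihood uses stochastic-approximation EM: per-animal
log-parameters are sampled by Metropolis kernels (one independence proposal
from the current population prior, then componentwise random-walk sweeps
with per-parameter scales adapted to 30–40% acceptance), and
`(theta_pop, Omega, sigma)` are updated in closed form from
stochastically-averaged sufficient statistics. Defaults: 300 exploration
iterations (step 1, with geometric annealing of `Omega` and `sigma` at 0.95
per iteration to keep exploration alive) and 200 smoothing iterations (step
`1/k`), 5 random-walk sweeps per iteration. A joint 4-D random walk was
tried first and mixes too slowly on the stiff, strongly correlated
`(alpha, beta)` posteriors — it stalls `sigma` at an inflated fixed point;
the componentwise kernel resolves this. `Omega` updates are projected to
the PSD cone (eigenvalue floor 1e-8). Divergence (non-finite population
mean) aborts with the trace attached.

Empirical Bayes estimates are per-animal MAP optimizations (Nelder–Mead on
log-parameters, warm-started from the final chain state). Diagnostics:
VPC (replicate cohorts simulated at the observed design points; 10/50/90
percentile bands with 95% envelopes), IWRES
`(ln y - ln f_hat)/(sigma |ln f_hat|)`, and eta-shrinkage
`1 - sd(eta_hat)/omega` (undefined and reported as NaN when `omega = 0`).
Standard errors: nonparametric bootstrap over animals (default B = 200,
refits may use shortened chains), or a Laplace-sandwich approximation from
per-animal marginal-likelihood scores for `theta_pop` and `sigma`.

Note the shrinkage statistic compares the EBE spread to the *population*
`omega`, so even a perfect estimator shows apparent shrinkage of order
`1/sqrt(2n)` from cohort sampling alone; the dense-design check uses 120
animals to keep that term below a few percent.

## Virtual-population regimen exploration

Treatment starts at day 27 (taken as the detection time), runs daily at a
given dose for 0–18 days, and surgery follows immediately after the last
dose; the horizon is day 85. For each regimen the explorer reports the
median-individual final burden (deterministic), the distribution of percent
change in primary-tumor size over the treatment window (median and 10–90%
band), and the fraction of virtual subjects whose day-85 burden reaches the
relapse threshold. The threshold is the 30th percentile of the *control*
arm's day-85 burden (30% mirroring the clinical metastatic-relapse fraction
in localized breast cancer); because burden is nondecreasing, the
at-horizon and first-passage definitions coincide (a `first_passage` flag
keeps the metastasis-free-survival reading explicit). Default cohort:
n = 1000, seeded; `k` is sampled per subject like the other random effects.

## Synthetic cohorts

The generator emulates the calibration study: eight arms (vehicle; 60
mg/kg for 3/7/14 days; 120 mg/kg for 3 days then 60 mg/kg for 0/4/8/11
days) in a 14-day presurgical window, surgery at day 34 (day 38 for the
validation groups), 13 animals per arm (104 total). Caliper measurements
run twice weekly from day 14 to surgery (primary tumor, mm^3),
bioluminescence weekly from surgery to day 85 (burden, photons/s); the real
per-animal sampling days are not published, so this cadence is a documented
stand-in typical of such studies. The photons/s-per-cell conversion is
likewise unpublished and defaults to 1; nothing downstream depends on it as
long as generation and fitting share the value. Ground-truth parameters are
always kept beside the noisy observations — generate → fit → compare is the
package's core validation loop. Exclusion events (failed resection, no
tumor take) are not simulated.

Biomarkers (Ki67, CD31, Ki67+/CD31+, Ki67+/CD31−, CTC, gMDSC, mMDSC) come
from a Gaussian copula whose correlation targets are stated on the observed
scale and moment-matched through the marginals (a log-normal marginal
attenuates Pearson correlation by `s/sqrt(e^{s^2}-1)`; targets infeasible
through a marginal are clamped with a warning). Defaults embed the two
strong observed redundancies — r(Ki67, Ki67+/CD31−) = 0.979 and
r(CTC, gMDSC) = 0.678 — and, deliberately, *no* association with `mu`
(`mu_association` plants a linear signal of chosen R^2 for positive
controls). Marginal shapes and scales are plausible inventions, not
published values; Ki67+/CD31− uses a near-normal count marginal because a
0.979 observed correlation with the normally-distributed Ki67 percentage
cannot be reached through a log-normal transform.

## Biomarker ML benchmark

Repeated 10-fold cross-validation (5 repeats) regressing `ln mu` on the
panel: intercept-only baseline (training-fold median), linear regression,
PLS (1–5 components), radial SVM (C in {0.25, 1, 4}, gamma by the scale
heuristic), random forest (500 trees, mtry in {2, 3, 5}), an extra-trees
forest as a second, randomized-split forest variant (no conditional-
inference forest implementation is used), and a single-hidden-layer network
(1/3/5 units, weight decay 0.1/0.01, L-BFGS). The hyperparameter grids are
not published; these are modest grids sized for cohorts of tens of animals.
Scaling and tuning are nested inside each training fold (inner 3-fold);
forests skip scaling. Metrics: per-resample RMSE and R^2 with 95% normal
CIs over the 50 resamples, relative prediction error on `ln mu`, and a
*paired* RMSE comparison against the baseline over the shared resamples —
an algorithm counts as significantly better only when the upper CI of the
paired difference is below zero. What the synthetic benchmark establishes
is the null/positive-control behavior (no false skill on independent
biomarkers; a planted R^2 = 0.8 signal is found); the real study's small
R^2 values are split- and data-dependent and are not reproduction targets.

## Problem sizes and tolerances

Simulation grid 0.05 day (0.1 day inside SAEM); SAEM acceptance experiments
use the 104-animal calibration design with 200 + 150 iterations and 4
sweeps; the shrinkage check uses 120 animals on the dense design; ML checks
use the study's n = 66. Deterministic reproductions of the published
forward-simulation numbers are asserted within 5% (burdens) and 10
percentage points (percent increases): the four interacting parameters are
published to three significant figures and their rounding propagates to a
few percent in these quantities.

## Known limitations

* The spatial density `rho` is never materialized in production (only the
  convolution); per-size statements beyond the test oracle need the
  characteristics evaluator.
* The K-PD concentration is a postulate, not measured PK; `Vd` and `ke` are
  fixed constants from the literature.
* Off-diagonal variability structure beyond the alpha–beta correlation is
  unavailable; relapse-threshold magnitudes inherit that uncertainty.
* The SAEM log-likelihood is reported via a Laplace approximation, adequate
  for monitoring but not for fine model comparison.
* Biomarker marginals are invented; only their correlation structure and
  (lack of) association with `mu` are study-anchored.
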