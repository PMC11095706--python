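# metanat

Mechanistic modeling of metastatic breast cancer under neoadjuvant therapy
(NAT), built around an ortho-surgical mouse model: a primary tumor is
implanted orthotopically, treated systemically (sunitinib) for a presurgical
window, surgically removed, and the post-surgical metastatic burden is
followed by bioluminescence. The package is for modelers and experimentalists
who want to simulate such studies, calibrate the model to longitudinal data,
explore treatment schedules in silico, and benchmark biomarkers against the
model's mechanistic parameters.

## Model

Primary tumor (`Vp`, cells; `1 mm^3 = 10^6` cells) and each metastasis grow
by the Gomp-Exp law

    g(v) = min( λv, (α − β ln(v/V₀)) v ),        V₀ = 1 cell,

an exponential cap λ (the in vitro proliferation rate) on a Gompertz law.
Treatment follows a kinetics-pharmacodynamics (K-PD) shortcut — the
concentration after each dose `Dᵢ` at `τᵢ` decays exponentially,

    C(t) = (1/V_d) Σᵢ Dᵢ e^{−k_e (t−τᵢ)} 𝟙_{t>τᵢ},

and scales the primary tumor's growth rate by `(1 − k C(t))`
(Norton–Simon); metastatic growth is unaffected by treatment. Cells
disseminate at rate `d(Vp) = μ Vp` and the total metastatic burden is the
convolution

    M(t) = ∫₀ᵗ d(Vp(t−s)) V(s) ds,

evaluated by FFT on a uniform grid (`V(s)` is the one-cell growth kernel).
Individual parameters `θᵢ = (αᵢ, βᵢ, kᵢ, μᵢ)` are log-normal with full
covariance; observations carry the study's log-proportional error
`ln y = ln f · (1 + σ̄ε)`. Population estimation is by SAEM; diagnostics
include VPC, IWRES, η-shrinkage and bootstrap/Laplace standard errors.
See `docs/methods.md` for the full account.

## Worked example

Simulate the median individual of the reference population under an 18-day
60 mg/kg NAT course (treatment from day 27, surgery at day 45) and compare
with immediate surgery at day 27:

```python
from metanat import (Schedule, default_population, default_grid,
                     simulate_individual)
from metanat.schedules import daily_schedule

pm = default_population()
grid = default_grid(85.0, 0.05)
g, kpd, met = pm.growth_params(), pm.kpd_params(), pm.met_params()

control = simulate_individual(
    g, kpd, met, Schedule(doses=(), resection_day=27.0, horizon=85.0), grid)
nat18 = simulate_individual(
    g, kpd, met, daily_schedule(60.0, 27.0, 18, 45.0, 85.0), grid)

print(f"MB(85d), surgery day 27:      {control.mb[-1]:.3e} cells")
print(f"MB(85d), 18-day NAT + surgery: {nat18.mb[-1]:.3e} cells")
print(f"increase: {100 * (nat18.mb[-1] / control.mb[-1] - 1):.1f} %")
```

Output:

```
MB(85d), surgery day 27:      2.760e+08 cells
MB(85d), 18-day NAT + surgery: 7.451e+08 cells
increase: 170.0 %
```

The drug shrinks the primary tumor, but because metastatic growth is
untreated, delaying surgery by 18 days still nearly triples the final
metastatic burden — the model's central, clinically uncomfortable
prediction for low-dose NAT.

A command-line layer wraps the common workflows:

```bash
metanat generate --out cohort/ --seed 1      # synthetic study (8 arms, truth kept)
metanat simulate --preset "Su60(14D)" --out traj.csv
metanat relapse --out regimens.csv --n 1000 --seed 1
```

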