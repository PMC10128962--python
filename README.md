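# gliopred

Model-based prediction of **diffuse low-grade glioma (LGG) regrowth after
radiotherapy (RT)** from sparse longitudinal MRI follow-ups.

LGGs are invasive, incurable brain tumors whose mean radiological radius
grows roughly linearly (a few mm/yr) until treatment. After RT the tumor
shrinks for anywhere between a few months and several years before
regrowing at its pre-treatment speed. Patients and clinicians care about
the *regrowth time* — the moment the radius reaches its post-RT minimum —
because it drives life planning and the scheduling of follow-up MRIs.
`gliopred` is for modelers and clinical researchers who want to estimate
that time as early as possible, ideally from the very first MRI after RT.

## The model

The mean tumor radius (mm) as a function of time `t` (years; `t = 0` at
the start of RT) is the 4-parameter analytical curve

    R(t) = R0 + v·t                      t < 0
    R(t) = R0 + v·t − k·(1 − e^(−t/τ))   t ≥ 0

with `R0` the radius at RT start, `v` the asymptotic radial growth speed
(bounded to the physiological 0.5–4 mm/yr), `k` the amplitude of the
RT-induced decay and `τ` its characteristic time. When the initial
collapse speed `v_d = k/τ` exceeds `v`, the radius has a minimum at the
closed-form regrowth time

    t_min = τ·ln(k/(τ·v)).

Fitting minimizes the measurement chi-square (±1 mm radius errors),
optionally augmented by an ensemble-derived Gaussian prior: the sample
covariance of fitted `(R0, v, k, τ)` across a reference cohort of 20
patients is diagonalized, `X = T·p` decorrelates the parameters, and
`Σ_i [(x_i − μ_i)/σ_i]²` is added to the objective. This prior makes the
problem solvable with as few as 3 measurements. A complementary *loose*
estimator fits only the pre/post-RT slopes and maps the collapse speed
through the empirical power law `t_min ≈ 9.0 / v_d^0.61`.

Monte-Carlo virtual patients (noisy synthetic measurements around a known
truth, refitted hundreds of times) quantify the uncertainty of either
estimator as a mean and a [5th, 95th] percentile interval.

## Worked example

```python
import numpy as np
import gliopred as gp

ens = gp.table1_ensemble()                       # 20-patient reference cohort
prior = gp.build_prior(ens, powerlaw=gp.fit_powerlaw(ens))
print(prior.powerlaw)
# PowerLaw(a=8.952658432777497, b=0.6186045323730491)

# a slow responder observed only at -6, 0 and +3 months
truth = ens.entries[14].params                   # t_min = 4.16 yr
design = gp.MeasurementDesign.from_months([-6, 0, 3])
dist = gp.mc_predict(truth, design, prior, n_reps=400, seed=0)
print(round(dist.mean, 2), tuple(round(x, 2) for x in dist.interval))
# 1.98 (1.36, 2.3)
```

Three months of post-RT data carry no curvature information for so slow a
responder, so the prediction collapses to the prior's typical regrowth
time (~2 yr) — the known failure mode for slow responders, and the reason
the loose slope/power-law estimator exists once a 12-month MRI is
available.

The same studies run from the shell:

```bash
gliopred mc --truth-table table1 --design "-6,0,3" --time-unit months \
    --reps 400 --seed 0 --out study.csv
gliopred build-prior fits.csv --out prior.json
gliopred fit followups.csv --mode constrained --prior prior.json
gliopred simulate --n-patients 50 --seed 7 --out synthetic.csv
```

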