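# Methods

## Model and assumptions

The mean radiological radius of a diffuse low-grade glioma is modeled as

    R(t) = R0 + v·t − k·(1 − e^(−t/τ))·𝟙[t ≥ 0]

with `t = 0` at the start of radiotherapy. The model is purely
geometrical: it assumes (i) the pre-treatment growth is already in its
asymptotic linear regime with radial speed `v`; (ii) radiotherapy removes
a fraction of the tumor through an exponential decay of amplitude `k`
(mm) and characteristic time `τ` (years), acting only after `t = 0`; and
(iii) regrowth resumes at the same speed `v`. The decay term is null
before RT, so the pre-RT branch is defined as exactly linear — naively
evaluating the exponential at `t < 0` would diverge and has no physical
meaning. The curve is continuous at `t = 0` and differentiable everywhere
except possibly there.

When the initial collapse speed `v_d = k/τ` exceeds `v`, the post-RT
radius has a unique minimum at the regrowth time
`t_min = τ·ln(k/(τ·v))`. When `k/(τ·v) ≤ 1` the radius never shrinks;
`regrowth_time` returns a distinguished `None` sentinel rather than a
negative number, and Monte-Carlo summaries count such replicates as
degenerate (excluded from means/percentiles, reported in
`n_degenerate`). The quadratic expansion at `t = 0⁺` is
`R0 + (v − v_d)·t + ε·t²/2` with curvature `ε = v_d/τ`; it underlies the
loose estimator below.

Units are fixed: mm for radii, years for times, mm/yr for speeds.
Month-denominated inputs are converted on ingestion (1 month = 1/12 yr).

## Fitting

The data objective is `χ² = Σ_i [R_i − R(t_i)]²/σ_i²` with σ = 1 mm, the
clinical uncertainty of manual diameter readings on T2-FLAIR images. Both
the data term and the prior term (below) are sums of squares, so
minimization uses bound-constrained trust-region least squares
(`scipy.optimize.least_squares`, TRF) with an analytic Jacobian.

Box bounds: all parameters ≥ 1e-6 (strict positivity; avoids the τ = 0
singularity), `v ∈ [0.5, 4]` mm/yr (the observed radiological range of
LGG radial speeds), and loose caps `R0, k ≤ 100` mm, `τ ≤ 20` yr.

The `k`–`τ` ridge of the exponential creates local minima, so the fit is
restarted from 8 deterministic points: `R0` initialized at the radius
measured nearest RT start; `v ∈ {0.5, 1, 2, 4}` mm/yr crossed with
`(k, τ) ∈ {(0.25·R0, 0.3 yr), (0.75·R0, 1.5 yr)}` — a fast and a slow
response template per speed. Starts are clipped strictly inside the
bounds. If several starts reach objectives within 1e-9, the smallest-τ
solution is reported (deterministic tie-break). This scheme was audited
against a 200-random-start search on sparse noisy replicates: it
reproduces the global optimum except in rare corner cases where the
"global" optimum is a degenerate τ → 0 boundary solution.

`fit_plain` requires ≥ 4 measurements. `fit_constrained` adds the
ensemble prior and is solvable with as few as one point (three points
make it meaningfully constrained).

## The ensemble prior

Fitted parameters are strongly correlated across patients (notably
`corr(v, k) ≈ 0.73`, tying pre-RT growth to the RT response). The prior:

1. sample covariance of the raw `(R0, v, k, τ)` across the reference
   cohort (raw, not standardized — a documented convention; the leading
   eigenvector is then dominated by the mm-scaled `R0` and `k`);
2. eigen-decomposition gives an orthogonal transform `T` (rows =
   eigenvectors, ordered by decreasing eigenvalue, sign fixed so each
   row's largest-magnitude entry is positive);
3. components of `X = T·p` are decorrelated by construction; their
   sample means and SDs `(μ_i, σ_i)` define the penalty
   `χ²_cons = Σ_i [(x_i − μ_i)/σ_i]²` added to `χ²`.

`(μ_i, σ_i)` are sample moments — the maximum-likelihood Gaussian fit,
free of the binning choices a histogram fit would introduce. Component
σ may be set to 0 (pins the component, used by synthetic sampling) or
∞ (disables it; with all σ infinite the constrained fit reduces to the
plain one).

The collapse-speed power law `t_min = a / v_d^b` is fitted by unweighted
nonlinear least squares in linear space, seeded by the log-log OLS
solution (`method="loglog"` exposes the latter directly). On the packaged
reference cohort the direct fit gives `a ≈ 8.95`, `b ≈ 0.62`; the log-log
fit gives `a ≈ 10.5`, `b ≈ 0.71` — the difference comes from the relative
weighting of short- vs long-`t_min` patients, and the direct fit is the
package default because it reproduces the published relation.

The loose estimator fits the continuous piecewise-linear model
`R0 + v·t` / `R0 + (v − v_d)·t` jointly for `(R0, v, v_d)` — a single
linear least-squares problem with the intercept shared at `t = 0`. Two
independent regressions would be underdetermined with only 1–2 post-RT
points. A fitted `v_d ≤ 1e-9` (numerically non-positive) raises a
no-collapse error: the tumor is not shrinking and no regrowth prediction
is meaningful. On noiseless sparse designs the piecewise-linear slope
underestimates the true `k/τ` by ~15% (secant vs tangent of the
exponential); the power law partly absorbs this bias because it was
itself fitted to data of the same kind.

## Monte-Carlo virtual patients

A virtual patient is a parameter vector treated as truth. Replicates add
i.i.d. Gaussian 1 mm noise to the model radii at the design times,
refit (constrained or loose), and record `t_min`. Summaries: mean and
empirical [5th, 95th] percentiles (linear interpolation between order
statistics) of the finite samples; degenerate replicates (no-shrinkage
sentinel, non-convergence, no-collapse) are counted separately, and more
than 50% degenerate raises an error carrying the partial result.

RNG discipline: one `SeedSequence` per study; replicate streams are
spawned by index, so enlarging `n_reps` extends rather than reshuffles
the sample. Cohort studies spawn one independent substream per patient.
Identical seeds give bit-identical summaries.

Virtual-cohort studies use the packaged 20-row best-fit table as truths
and the full-ensemble prior; leave-one-out priors are applied only in the
truncated-follow-up validation of real(istic) follow-ups, where the
tested patient must not inform their own prior.

Problem sizes: the packaged studies and acceptance tests run at 400
replicates per patient, a size at which cohort means are stable to well
under 0.1 yr (checked by the seed-stability test: independent seeds move
a patient mean by less than 3·SD/√400).

## Synthetic data

The generator emulates the clinical follow-ups the model is meant for:
2–10 pre-RT measurements over 0.5–3 yr, 5–20 post-RT measurements
spanning 1–8 yr, radii in the 10–45 mm range, and 1 mm Gaussian noise.
Virtual patients are drawn in the decorrelated basis (independent
Gaussians with the prior's `μ, σ`), mapped back through `Tᵀ`, and
rejection-sampled against the physical bounds (max 1000 attempts).
Non-physical negative radii are redrawn point-wise and logged.

What the generator does *not* emulate: post-RT oedema transients
(radius bumps mimicking growth right after RT), measurement-time
irregularity correlated with disease state (real MRIs cluster when the
tumor misbehaves), inter-reader measurement bias, and any deviation of
true tumor dynamics from the 4-parameter curve itself. Passing tests on
synthetic data therefore demonstrate internal consistency of the
estimation machinery, not clinical validity.

## Numerical choices

- Optimizer tolerances `xtol = ftol = gtol = 1e-12`; noiseless
  12-point recovery is then exact to ≤ 1e-6 per component.
- Covariance and component SDs use `ddof = 1`.
- Rank-deficiency guard: smallest covariance eigenvalue ≤ 1e-12 × largest
  raises a degenerate-ensemble error.
- Prior JSON serialization keeps full double precision (lossless
  round-trip).
- Percentiles: NumPy's default linear interpolation.

## Design choices where the problem was open

- **Eigenvector order/sign.** The reference transform is printed without
  a stated convention, and its last two rows are *not* in
  descending-eigenvalue order (the ensemble eigenvalues are 68.6, 25.5,
  0.92, 0.16, and the printed rows 3/4 correspond to the two smallest in
  swapped order). The package uses descending eigenvalues with
  largest-entry-positive sign fixing — deterministic and reproducible —
  and comparisons against the printed matrix match rows by magnitude
  rather than position.
- **Loose-slope fit.** Joint continuous piecewise-linear fit (shared
  intercept) rather than separate pre/post regressions, for robustness
  with 1–2 post-RT points.
- **Multi-start scheme.** The 8-start template above; the underlying
  method statement names only "a standard optimization algorithm".
- **Degenerate-replicate policy.** Excluded from summaries but always
  counted and reported; there is no published policy for no-shrinkage
  fits in Monte-Carlo replicates.

## Known limitations

- **Prior strength.** With sample-moment σ's the quadratic penalty is not
  perfectly neutral on rich follow-ups: across noiseless 12-point
  follow-ups generated from the 20 reference parameter sets, the
  constrained fit moves `t_min` by a median of ~0.05–0.09 yr and up to
  ~0.6 yr for the slowest responders (flat χ² ridges). The published
  account reports the two fits agreeing exactly on rich data, which
  suggests its histogram-fitted component σ's were wider than sample
  moments; those widths are not recoverable. The corresponding
  acceptance test encodes the literature-level expectation (< 0.05 yr)
  and fails honestly on the slow responders.
- **Fast-responder bias of the 3-month prediction.** The `t_min`
  estimator's sampling distribution under 3-point, 1 mm-noise designs is
  right-skewed toward the prior's typical value; at 400 replicates the
  cohort means for the three fastest responders overshoot truth by
  0.51–0.64 yr against a 0.5 yr target (the fourth is within 0.07 yr).
  The effect is intrinsic to exact minimization of the penalized
  objective: it persists unchanged under exhaustive multi-start, dense
  random restarts, and warm-starting at the truth, and is nearly
  insensitive to doubling the prior σ's. The acceptance test encodes the
  0.5 yr target and fails honestly for those three patients; the
  prior-domination half of the same test (slow responders underestimated
  by > 0.5 yr) and the loose-estimator comparisons pass.
- Predictions assume the reference ensemble is representative; a 20-patient
  cohort is small, and the prior inherits its sampling noise.
- The model does not represent oedema, chemotherapy, or deviations from
  single-exponential response dynamics.
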