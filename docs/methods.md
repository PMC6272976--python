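# Methods note

This note documents the statistical and numerical choices in `fermkin`:
the models, their assumptions, the parameter conventions and defaults, what
the synthetic-data generators do and do not represent, and the known
limitations. It describes only what the code computes.

## 1. Plackett–Burman screening (`fermkin.doe.pb_effects`)

**Model.** For a two-level design matrix with columns coded ±1, the effect
of factor *j* is the contrast

effect_j = mean(y | x_j = +1) − mean(y | x_j = −1),

and the regression coefficient is effect_j / 2. The design must be
balanced: each assigned column must contain equal numbers of +1 and −1
runs (checked with a 10⁻⁹ tolerance so that real-unit levels encoded to
coded units survive floating-point round-off).

**Error estimate.** Designs may reserve *dummy columns* — unassigned
contrasts that estimate pure error. The effect standard error is

SE = sqrt( Σ_d effect_d² / n_dummies ),

with n_dummies degrees of freedom for the *t* statistic (3 for the packaged
12-run design). Callers may override the significance threshold via
`t_limit`; the default is the two-sided 5% critical value at the
dummy-based degrees of freedom. `analysis/01_screen_factors.py`
additionally reports against a threshold of 2.36462 (the 5% value at 7
degrees of freedom, i.e. pooling dummies with the smallest real effects);
both thresholds select the same factor set on the packaged table.

**Assumptions.** Effects are additive and two-level; interactions alias
onto main effects as in any resolution-III design; responses are
homoscedastic across runs.

## 2. Quadratic response surface (`fit_quadratic`, `anova_quadratic`, `optimize_quadratic`)

**Coding.** Real factor levels map to coded units by
x = (real − center) / halfwidth, declared per factor in a `FactorSpec`.
The packaged Box–Behnken table stores coded levels directly
(`columns_coded: true` in its config); user tables may be in real units.

**Model.** Full quadratic in coded units, fitted by ordinary least squares
(`numpy.linalg.lstsq`). Term order is fixed: intercept, linear terms,
pairwise interactions with i < j, then squares. A design whose model
matrix is rank-deficient raises `SingularDesignError` rather than
returning one of infinitely many solutions.

**ANOVA.** Sums of squares are *partial* (extra) sums of squares: each
term's SS is the increase in residual SS when that term alone is dropped
from the full model. Model and residual SS add to the total (corrected)
SS. Pure error comes from replicate groups — runs with identical coded
rows — and lack-of-fit is residual minus pure error. F statistics are
reported only where the denominator mean square is positive and has
positive degrees of freedom; on noiseless synthetic data the residual MS
is zero and the F column is left empty rather than infinite.

**Optimization.** The stationary point solves H x = −g with
H_ii = 2 β_ii, H_ij = β_ij, g = linear coefficients. If H is negative
definite (for maximization) and the stationary point lies inside the coded
box, it is returned exactly. Otherwise the surface is optimized with
L-BFGS-B from a fixed, deterministic grid of start points (all corners,
face centers and the origin of the coded box), and the best bounded
optimum is returned with `on_boundary` flagged. Optima are reported in
both coded and real units when factor specs are available.

## 3. Batch kinetics (`fermkin.kinetics`)

**Growth.** Logistic: dX/dt = μₘ X (1 − X/Xₘ), with closed form

X(t) = X₀ Xₘ / (X₀ + (Xₘ − X₀) e^(−μₘ t)),

evaluated in a numerically stable rearrangement. Fitted with
`scipy.optimize.least_squares` from data-driven initial values
(X₀ from the first sample, Xₘ from the maximum, μₘ from the steepest
log-slope), with positivity bounds. An optional `t_max` truncates decline
phases that the logistic model cannot represent.

**Product.** Luedeking–Piret: dP/dt = α dX/dt + β X. Its integral given
logistic growth is

P(t) = P₀ + α (X(t) − X₀) + β (Xₘ/μₘ) · ln( (Xₘ − X₀ + X₀ e^(μₘ t)) / Xₘ ),

where the logarithm is computed via `numpy.logaddexp` to avoid overflow at
large μₘ t. Because P(t) is linear in (α, β, P₀) once the growth
parameters are fixed, the fit is a linear least-squares solve (two-stage
estimation). By default P₀ = 0, so P(0) = 0; `fit_p0=True` adds the
baseline as a third linear parameter. A biomass trajectory that is
numerically flat makes α and β unidentifiable (the two regressors become
collinear); this is detected with an SVD-based rank check (singular values
below 10⁻¹⁰ of the largest are treated as zero) and raises rather than
returning arbitrary coefficients.

**Gaden classification** (`classify_gaden`). Type I if β ≈ 0 and α ≠ 0
(growth-associated), type III if α ≈ 0 and β ≠ 0
(non-growth-associated), type II otherwise. "≈ 0" means |coefficient| ≤
`tol`, default `GADEN_ZERO_TOL = 0.005` — half a unit in the third
decimal, i.e. the precision at which such coefficients are conventionally
reported. Both coefficients ≈ 0 raises `NoProductionError`.

**Parameter meta-models** (`fit_param_surface`). Kinetic parameters can be
regressed on the operating conditions — inoculum I (mL), temperature T
(°C), stirring speed R (r/min) — with a user-declared polynomial term list
(e.g. `["1", "I", "T", "R", "T^2"]`). The model-matrix rank is checked
first: if rank < number of terms the design cannot identify the model and
`UnderdeterminedDesignError` is raised, unless `allow_rank_deficient=True`
explicitly requests the minimum-norm solution (flagged in the result).
Nine one-factor-at-a-time condition points span rank 7, so the 10-term
full three-variable quadratic is structurally underdetermined on that
design; see `analysis/04_parameter_meta_models.py`.

## 4. Assay arithmetic (`fermkin.assay`)

Enzyme activity from a DNS absorbance reading:

EA = (A · 640.5 + 13.99) · V · n / (v · T),

with A the absorbance at 540 nm, V the reaction volume (mL), n the
dilution factor, v the enzyme volume (mL) and T the reaction time (min);
one unit (U) is 1 μg of reducing sugar (galactose equivalent) released per
minute. The calibration slope (640.5) and intercept (13.99) are defaults
of one published standard curve and are overridable per instrument.
Apparent viscosity is η = k · reading, with k the rotor constant. Inputs
are validated (positive volumes and times, non-negative absorbance);
violations raise `InvalidReadingError`.

## 5. Synthetic data (`fermkin.synthdata`)

Generators draw from `numpy.random.default_rng(seed)` and are fully
deterministic given the seed.

- `simulate_fermentation` evaluates the closed-form logistic and
  Luedeking–Piret curves on a fixed grid (0–72 h, step 4 h by default) and
  adds independent Gaussian noise: biomass SD 0.01 OD600, product SD
  3 U/mL by default.
- `simulate_doe` evaluates a declared quadratic surface on a Box–Behnken
  design (edge pairs at ±1 with all other factors at 0, plus center
  replicates) and adds Gaussian noise; the default SDs (5.9 U/mL for
  activity, 0.0034 OD600 for biomass) equal the observed center-replicate
  standard deviations of the packaged table.

**What the synthetic data shows.** That the estimators invert the
generators: fits on simulated data recover the declared truth to within
noise, exactly in the noiseless limit, and with vanishing bias as noise or
replication grows. **What it does not show:** anything about real
cultures. The noise is additive, Gaussian, homoscedastic and independent
across time points; real fermentations have autocorrelated, often
multiplicative errors, lag phases, decline phases and model misfit that
these generators deliberately exclude.

## 6. Design decisions

- Two-stage kinetics (growth first, then a linear solve for α, β) instead
  of a joint nonlinear fit: it is the standard practice for this model
  pair, is convex in the second stage, and makes the α/β identifiability
  check exact.
- Partial rather than sequential sums of squares, so that each term's SS
  is invariant to term order.
- All fits refuse rank-deficient designs by default instead of silently
  returning a minimum-norm solution.
- Standard library building blocks are used throughout — `numpy.linalg`
  for linear algebra, `scipy.optimize` for nonlinear fitting and bounded
  optimization, `scipy.stats` for t/F tail probabilities — rather than
  reimplementations; the package's own code is the experimental-design and
  kinetics logic these do not provide.

## 7. Known limitations

- **Biomass-surface R² mismatch (deliberately failing test).** The
  quadratic fit of the biomass response on the packaged 29-run table has
  R² = 0.9897. The reference value asserted in the acceptance suite is
  0.9700, which is internally inconsistent with the reference ANOVA sums
  of squares (model ≈ 0.054 of total ≈ 0.055 implies R² ≈ 0.989, and
  the adjusted R² is 0.979 — neither is 0.97). The same fit reproduces
  every reference coefficient, the activity-surface R², the ANOVA sums of
  squares and both optima, so the computation is retained as is and the
  one assertion is left failing rather than tuned to pass.
- **Gaden classification is a point-estimate rule.** With the strict
  default tolerance (0.005), measurement noise alone makes a truly
  growth-associated fermentation (β = 0) classify as type II: at product
  noise of 3 U/mL the refit β̂ scatters by ~0.2. Classifying noisy fits
  requires a tolerance at the noise scale of the estimate (as done in
  `analysis/03_fit_kinetics.py`) or replicate-based inference, which the
  package does not implement.
- The logistic model has no lag or death phase; `t_max` truncation is the
  only mitigation offered.
- Meta-models over operating conditions are descriptive least-squares
  fits on at most nine points; they carry no inferential error bars.
- ANOVA p-values assume independent homoscedastic Gaussian errors; the
  packaged tables provide no way to test that assumption.
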