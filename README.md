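# fermkin

Design-of-experiments and fermentation-kinetics toolkit for microbial
enzyme production, built around a κ-carrageenase fermentation case study:
screening a growth medium with a Plackett–Burman design, refining it with a
Box–Behnken response surface, and modeling batch growth and product
formation with logistic / Luedeking–Piret kinetics.

## The problem

A marine bacterium secretes κ-carrageenase, an enzyme that hydrolyzes
κ-carrageenan. Enzyme yield depends strongly on the medium composition
(carbon source, nitrogen sources, salts) and on the operating conditions
(temperature, stirring speed, inoculum size). The package implements the
standard workflow for optimizing such a process:

1. **Screening** (`fermkin.doe.pb_effects`): a 12-run, 8-factor
   Plackett–Burman design identifies which medium components matter. Each
   factor's effect is the contrast between its high- and low-level run
   means; the standard error is estimated from three unassigned dummy
   columns, giving a *t* test with 3 degrees of freedom.
2. **Response-surface optimization** (`fit_quadratic`, `anova_quadratic`,
   `optimize_quadratic`): a 29-run, 4-factor Box–Behnken design (24 edge
   points + 5 center replicates) supports a full quadratic model in coded
   units,

   *y* = β₀ + Σ βᵢxᵢ + Σ βᵢⱼxᵢxⱼ + Σ βᵢᵢxᵢ²,

   fitted by ordinary least squares. ANOVA partitions the residual into
   lack-of-fit and pure error (from the center replicates), and the fitted
   surface is maximized over the coded cube — analytically at the
   stationary point when the Hessian is negative definite, otherwise by
   deterministic multistart bounded optimization.
3. **Batch kinetics** (`fermkin.kinetics`): biomass follows logistic
   growth, d*X*/d*t* = μₘ*X*(1 − *X*/*X*ₘ), fitted by nonlinear least
   squares; product formation follows the Luedeking–Piret law,
   d*P*/d*t* = α d*X*/d*t* + β*X*, whose integrated form is linear in
   (α, β) given the growth parameters. The fitted (α, β) pair classifies
   the fermentation into Gaden type I (growth-associated, β = 0), type II
   (mixed) or type III (non-growth-associated, α = 0).
4. **Assay arithmetic** (`fermkin.assay`): converts DNS
   (3,5-dinitrosalicylic acid) absorbance readings into enzyme activity in
   U/mL, and rotor readings into apparent viscosity.
5. **Synthetic data** (`fermkin.synthdata`): seeded generators that
   simulate fermentation time series and DOE response tables from declared
   ground truth, used throughout the test suite for round-trip validation.

Reference designs (the screening table, the Box–Behnken table and a table
of kinetic parameters across nine operating conditions) ship as packaged
fixtures under `src/fermkin/data/` and load via `fk.load_pb_fixture()`,
`fk.load_bbd_fixture()` and `fk.load_kinetic_params_fixture()`.

## Worked example

```python
import fermkin as fk

# 1. screening: which factors move enzyme activity?
pb = fk.load_pb_fixture()
screen = fk.pb_effects(pb, "EA")
print(screen.factors.round(3))
```

```text
        coefficient  effect  t_value  p_value  significant
factor
A            36.832  73.665   21.999    0.000         True
B             8.164  16.328    4.876    0.016         True
C            12.498  24.995    7.464    0.005         True
D            -1.374  -2.748   -0.821    0.472        False
E            20.286  40.572   12.116    0.001         True
F             3.453   6.905    2.062    0.131        False
G             2.684   5.368    1.603    0.207        False
H             3.793   7.585    2.265    0.108        False
```

```python
# 2. response surface over the four screened factors
table = fk.load_bbd_fixture()
fit = fk.fit_quadratic(table, "EA")
opt = fk.optimize_quadratic(fit, factors=table.factor_specs)
print(f"R^2 = {fit.r_squared:.4f}")
print(f"max predicted activity: {opt.predicted_response:.1f} U/mL")
print("at", {k: round(v, 2) for k, v in opt.real_location.items()})
```

```text
R^2 = 0.9684
max predicted activity: 267.9 U/mL
at {'X1': 1.76, 'X2': 20.05, 'X3': 0.96, 'X4': 1.02}
```

```python
# 3. kinetics: simulate a batch from known truth, then refit it
truth = fk.FermentationTruth(
    growth=fk.LogisticParams(x0=0.016, xm=0.655, mu_m=0.214),
    product=fk.LPParams(alpha=330.606, beta=16.432),
)
biomass, product = fk.simulate_fermentation(truth, seed=7)
g = fk.fit_logistic(biomass)
lp = fk.fit_lp(g.params, product)
print(f"mu_m = {g.params.mu_m:.3f} 1/h, Xm = {g.params.xm:.3f} OD600 "
      f"(R^2 = {g.r_squared:.3f})")
print(f"alpha = {lp.params.alpha:.1f}, beta = {lp.params.beta:.1f} "
      f"-> Gaden type {lp.params.gaden_type}")
```

```text
mu_m = 0.220 1/h, Xm = 0.652 OD600 (R^2 = 0.999)
alpha = 328.5, beta = 16.6 -> Gaden type II
```

The same operations are exposed on the command line:

```sh
$ fermkin ea --A 0.35 --V 10 --v 0.5 --T 10
{"EA_u_per_ml": 476.33000000000004}
$ fermkin classify --alpha 458.271 --beta 0.0
{"alpha": 458.271, "beta": 0.0, "gaden_type": "I"}
```

See `fermkin --help` for the full subcommand list (`pb`, `rsm`,
`fit-growth`, `fit-product`, `classify`, `param-surface`, `ea`,
`simulate`).

## Repository layout

This is an analysis project: the reusable library lives in `src/fermkin/`,
and the analyses are numbered scripts under `analysis/` that run top to
bottom and write their outputs to `results/`:

| script | question | outputs |
|---|---|---|
| `analysis/01_screen_factors.py` | which medium factors matter? | `results/pb_effects_*.tsv` |
| `analysis/02_fit_response_surface.py` | where is the optimum medium? | `results/rsm_*.{tsv,json}` |
| `analysis/03_fit_kinetics.py` | do the kinetic fits recover known truth? | `results/kinetics_refit.csv` |
| `analysis/04_parameter_meta_models.py` | which parameter meta-models are identifiable? | `results/meta_model_fits.csv` |

Each script's docstring states its question and findings; run them with
`python analysis/0N_*.py`.

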