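# memlag

Pooled (panel) time-series modelling of daily habit counts — how long
does a behavioural habit "remember" its own past?

`memlag` is built for intensive-longitudinal designs in behavioural and
health research: each of J subjects keeps a daily diary of a count
(here, cigarettes smoked) for a couple of months, and the question is
how today's count depends on previous days, on the day of the week, and
on who the subject is.  Analysing each short series alone has little
power; pooling all subjects into one panel model recovers small,
long-range effects — at the price of having to deal with strong
between-subject heteroscedasticity first.

## The model

Raw counts Y_t,j are first made comparable across subjects by dividing
each subject's series by its own sample SD s_j,

    Yᴴ_t,j = Y_t,j / s_j ,

so every subject has within-subject variance exactly 1 (subjects are
*not* mean-centred; level differences are absorbed by the lag terms).
The pooled homoscedastic series is then modelled as a seasonal
autoregression with day-of-week effects,

    Yᴴ_t,j = b₀ + Σ_k b_k · Yᴴ_{t−k,j} + Σ_d β_d · D_d(t) + ε_t,j ,

with lags k ∈ {1, 2, 7, 14, 21, 28, 35, 42, 49, 56} (a 2-day short
memory plus eight weekly seasons) and six weekday dummies D_d with
Sunday as the reference.  Estimation is Gaussian maximum likelihood of
the joint mean + covariance structure of (response, lags) under three
substantive constraints, each independently toggleable:

1. **order** — b₁ ≥ b₂ ≥ 0 and b₇ ≥ b₁₄ ≥ … ≥ b₅₆ ≥ 0 (the longer ago,
   the weaker the effect; all effects non-negative),
2. **equal variances** of all lagged predictors (they are lags of one
   variable),
3. **covariances by distance** — Cov(lag_j, lag_k) depends only on
   |j − k| days (Toeplitz-by-distance).

A model ladder mirrors the analysis sequence: the multilevel **M1**
(random intercept and random slopes for lags 1 and 7, level-2 gender
and age) is attempted first; the fixed pooled **M2** (lags + weekday),
**M3** (lags only) and the zero-covariance null **M0** are always
fitted and compared by SEM-style fit indices (χ²/df, RMSEA with 90% CI,
CFI, TLI, SRMR, AIC), nested Δχ² tests, and residual diagnostics
(Lilliefors/KS normality, pooled Ljung–Box over three weekly seasons).
The memory span itself is read off the pooled partial autocorrelation
function: the largest lag whose PACF exceeds the 1/√N white-noise band.

A fully parameterised synthetic generator (`memlag.simulate`) produces
panels with exactly this structure — heteroscedastic subjects, seasonal
AR dynamics, weekday profile, MCAR missingness — so the whole pipeline
is testable end to end with known ground truth.

## Worked example

```python
import memlag as ml

dataset, truth = ml.simulate_panel(ml.default_config(seed=1))
design = ml.build_lag_design(ml.homoscedastic_transform(dataset), ml.LagSpec())
m2 = ml.fit_pooled(design, ml.model_m2())
m3 = ml.fit_pooled(design, ml.model_m3())
print(m2.params.loc[["lag_1", "lag_7", "d_mon"], ["estimate", "se", "p"]].round(4))
print(f"R2 = {m2.r2:.3f};  AIC M2 = {m2.aic:.1f} vs M3 = {m3.aic:.1f}")
d, ddf, p = ml.nested_chi2_test(m3, m2)
print(f"day-of-week block: delta chi2({ddf}) = {d:.1f}, p = {p:.2g}")
```

prints (seed 1):

```
       estimate      se    p
term
lag_1    0.2659  0.0236  0.0
lag_7    0.2106  0.0247  0.0
d_mon   -0.6344  0.0909  0.0
R2 = 0.845;  AIC M2 = 46943.3 vs M3 = 47002.7
day-of-week block: delta chi2(6) = 71.4, p = 2.1e-13
```

Read: yesterday's consumption carries a weight of ≈ 0.27, the same
weekday one week ago ≈ 0.21 (both on the unit-variance scale), Mondays
run ≈ 0.63 SD below Sundays conditional on the lags, the model explains
≈ 84% of the variance of the pooled daily counts, and dropping the six
weekday terms worsens both AIC and the nested χ².

The `examples/` directory holds one short script per capability
(simulation, descriptives, correlogram/memory span, model ladder,
residual diagnostics, full pipeline); each prints what it computes and
what the numbers mean.  A thin CLI covers the same ground from a shell:

```bash
memlag simulate --seed 1 --out sim/
memlag run --in sim/panel.csv --out report/
```

Real data enter through `read_panel_csv` (long format: subject, day
index, optional weekday, count; a column-mapping config absorbs
arbitrary headers) or `to_longitudinal` (person-level wide tables).
Missing days keep their row and are never imputed; lag construction
applies listwise deletion.

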