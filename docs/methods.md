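# Methods

This note documents the statistical model behind `memlag`, the design
choices that were genuinely open, the numerical conventions, and what
the synthetic generator does and does not emulate.

## Data model

A panel holds J subjects, each with a gapless 1-based daily grid of
length n_j and a weekday label that advances cyclically.  Missing days
keep their row (NaN count); nothing is imputed at any stage — missing
values only ever remove rows from downstream computations (listwise
deletion in the lag design, pair deletion in the correlogram).  Day
indexing is deliberately minimal: the model needs only order and
weekday, so calendar dates are out of scope and weekdays can be derived
from a configured start weekday when a file lacks them.

## Per-subject rescaling

Subjects differ by an order of magnitude in dispersion, which breaks
the homogeneity assumptions of pooled Gaussian ML and inflates
between-subject Levene tests into the hundreds.  Each subject is
therefore divided by its own sample SD s_j (n−1 denominator, all
non-missing days), giving within-subject sample variance exactly 1.
Two conventions worth stating:

* subjects are **not mean-centred** — between-subject level differences
  persist on purpose and are absorbed by the (highly persistent) lag
  terms, which is also why the pooled intercept is small;
* s_j is computed over *all* non-missing days, including the first
  max-lag days that the design later consumes as burn-in.

A constant series (s_j = 0) is a named error, not a silent drop.

## The seasonal lag model and its constraints

On the rescaled scale, the response at (subject j, day t) is regressed
on lags {1, 2} ∪ {7m : m = 1..8} of the same subject and six weekday
dummies (Sunday reference).  Three substantive constraints encode the
habit hypothesis:

1. **Order.**  Within the non-seasonal chain (b_1 ≥ b_2 ≥ 0) and the
   seasonal chain (b_7 ≥ … ≥ b_56 ≥ 0), effects weaken with distance
   and are non-negative (an incremental, "model-free" habit; negative
   coefficients would signal compensatory regulation).
2. **Equal variances** of the lag predictors.
3. **Covariances by distance**: Cov(lag_j, lag_k) is a function of
   |j − k| only, giving ~24 distinct covariance parameters instead
   of 45.

### Estimation

The fitted object is the Gaussian ML of the joint mean + covariance
structure of z = (response, lags), with the dummies as fixed
regressors.  Parameterised conditionally, the likelihood factorises
exactly into

* the **regression block** p(y | x, D): order-constrained least squares.
  Each chain is reparameterised by non-negative increments
  (b_i = Σ_{l≥i} e_l, e ≥ 0), making the problem a bounded linear
  least-squares solved exactly (BVLS).  Active increments (e_l = 0) are
  reported; with no active constraint the solution is OLS.
* the **covariance block** p(x): minimisation of
  log|Σ(θ)| + tr(S Σ(θ)⁻¹) over the class parameters (one shared
  variance, one covariance per distance), by L-BFGS-B with the analytic
  gradient, started at the class means of S (the least-squares
  projection, typically already near the optimum).  Non-positive-
  definite proposals are repelled by a minimum-eigenvalue penalty.

Because the two blocks share no parameters, this two-stage computation
*is* the exact joint ML, and with every constraint disabled it
coincides with OLS plus the sample covariance matrix (the test suite
asserts agreement to 1e-8).

Standard errors are the observed-information ones of the unconstrained
parameterisation evaluated at the constrained solution (the chain map
is an invertible linear reparameterisation, so the delta method returns
the usual ψ̂ (X'X)⁻¹ form); no polyhedral constraint-adjusted inference
is attempted, and SEs of coefficients sitting on an active constraint
should be read with that in mind.  p-values are one-sided for
sign-constrained lag terms, two-sided elsewhere, on the normal
reference.  Standardised estimates are raw × SD(predictor)/SD(response)
on the analysis rows.  R² is 1 − ψ̂/Var(y).

### Fit indices and degrees of freedom

χ² = 2(llsaturated − llmodel), where the shared saturated model is the
unconstrained regression on the full term set plus the free covariance.
Observed statistics are counted as: unique covariances of z (66 for 11
variables) + means (11) + dummy slopes (6) = 83; free parameters are
counted per model (M2 under all constraints: 7 mean + 10 lag + ψ + 10
lag means + 1 variance + 24 distance covariances = 53, so df = 30).
Inequality (order) constraints consume no df.  This accounting is
internally consistent — M3 is nested in M2 with Δdf = 6 — but it is
*not* the bookkeeping of every SEM package; df values from software
that counts moments differently will not match, and the package never
claims them.  RMSEA = √(max(0, χ²−df)/(df·N)) with the 90% CI from
noncentral-χ² inversion; CFI/TLI use the zero-covariance null of the
same variable set (diagonal covariance, intercept-only mean) as
baseline; SRMR is the RMS standardised residual of the unique moments
of (ỹ, x), where ỹ is the response with the fitted dummy part removed
(so a correctly specified structure gives near-zero residuals).

### Multilevel path

The random-coefficient hypothesis (random intercept, random slopes for
lags 1 and 7, level-2 gender/age) is estimated with `statsmodels`
MixedLM by ML under a bounded iteration budget, trying three optimisers
and keeping the best *finite*-likelihood solution (one optimiser is
known to exit with a degenerate infinite log-likelihood; such exits are
never selected).  Non-convergence and boundary (≈0) random-effect
variances are reported as outcomes — "degenerate: collapses to fixed
model" — rather than raised, because on data generated by one shared
model that is the scientifically expected result.

## Correlogram and memory span

Pooled autocorrelations form cross-products strictly within subjects,
sum them across subjects, and normalise by the pooled lag-0 sum of
squares; N_eff,k counts the pairs actually available at lag k, and the
significance band is ±z₀.₉₇₅/√N_eff,k.  Subjects are demeaned by their
own mean by default (otherwise level differences masquerade as
correlation at every lag); global and no demeaning are available for
sensitivity and for residual panels.  The PACF comes from the
Durbin–Levinson recursion on the pooled ACF.

The **memory span** is the largest lag whose correlation exceeds the
band, and the span scan is **positive-sided by default**.  Two reasons:
the substantive hypothesis is one-sided (past consumption raises
present consumption; the model constrains all lag coefficients ≥ 0),
and within-subject demeaning biases every pooled r_k slightly downward
(≈ −Var(subject window mean)/γ₀), which for a persistent process
produces small systematically *negative* PACF values just above the
true order that a two-sided rule flags spuriously.  The span should be
read from the PACF: the ACF of a persistent AR does not cut off at the
model order, so the ACF span runs to the end of whatever window is
computed, while the PACF span identifies the order (56 days under the
default generator, at large panel sizes).

## Residual diagnostics

Normality: Kolmogorov–Smirnov against a normal with the residuals' own
mean/SD; the headline p-value is Lilliefors-corrected (table-based),
with the naive fully-specified p reported alongside (it is optimistic).
Note the per-subject rescaling makes pooled residuals a mild scale
mixture of normals, so very large samples can flag small D values.

Whiteness: a pooled Ljung–Box over seasons × period lags (default
3 × 7 = 21).  The statistic is

    Q = N (N + 2) Σ_k r̂_k² / N_eff,k ,

which reduces exactly to the classical single-series formula
(n(n+2) Σ r̂²/(n−k)) when J = 1 and matches the sampling variance
N_eff,k/N² of pooled autocorrelations under the null (a scalar-N
weighting would mis-calibrate by the factor (N−k)/(N−Jk)).  Residual
autocorrelations use within-subject products with a single *global*
centring: model residuals are already centred by the fitted intercept,
and re-demeaning each short subject series separately would bias every
r̂_k by ≈ −J(n̄−k)/(n̄N) and inflate Q by ~10 points at study scale,
destroying the test's 5% calibration (the suite verifies 5% ± 2 points
over 1,000 null replicates).  df = number of lags with no
fitted-parameter correction by default; a correction is available
behind a flag.

## Synthetic generator

Per subject: a record length from {69..91} with mass 46/62 on 84, a
start weekday uniform on 7, a latent homoscedastic mean
m_j ~ N(4.546, √1.253), a raw scale s_j ~ logNormal(log 3.45 − 0.35²/2,
0.35), and the recursion

    y_t = c_j + Σ_k b_k y_{t−k} + d_w(t) + σ_ε ε_t

with the default b_k and d_w equal to the fitted habit-model values
(lag weights summing to 0.9839), c_j solved from a 7×7 linear system so
the subject's stationary weekly mean equals m_j, initialisation at the
stationary weekday profile, and a 200-day burn-in (> 3× the 56-day
memory) discarded.  Raw counts are y_t · s_j, optionally rounded and
floored at zero (off by default: the fitted model is linear-Gaussian
and rounding is a realism toggle), then MCAR missingness at 1.08%.
Gender (36:26) and age (18–26) labels are generated with no effect on
the counts.

**AUTO innovation variance.**  σ_ε is solved analytically from the
Yule–Walker system so the stationary within-subject variance
(autoregressive γ₀ plus the deterministic weekday-profile variance)
equals 1, the scale on which the default coefficients are expressed.
An important consequence of the near-unit-root persistence: an 84-day
window *expresses* far less than the stationary variance (the expected
window sample variance, computable via `expected_sample_variance`, is
≈ 0.44 here, because the slow components wander the window mean).  The
per-subject rescaling of the analysis divides exactly this realised
sample SD out again, so **lag-coefficient recovery is unaffected** —
but quantities pinned to the realised scale shift: simulated
homoscedastic grand means come out around 7 rather than ≈ 4.5, realised
total variance around 5, and recovered weekday effects scale by
≈ 1/0.66 relative to the generating d_w.  The package chooses the
stationary-variance convention because it keeps the generating
coefficients, the fitted coefficients, and the model's explained
variance mutually consistent; the alternative (pinning the window
sample variance to 1) makes means and weekday effects land on target
but caps the achievable R² near 0.74.  No single configuration of this
process can reproduce every printed-scale descriptive at once; the
tests assert the quantities that are well-defined under the convention
(coefficient recovery, window-variance prediction, R², memory span).

What the generator does **not** emulate: count-valued (Poisson-like)
noise by default, autocorrelated or informative missingness,
covariate-driven heterogeneity, raw-scale weekday descriptives (the
marginal weekday profile implied by the conditional weekday effects
orders differently from raw weekday means), or any drift or
non-stationarity.  Passing tests therefore validate the estimator and
pipeline under the stated stationary Gaussian conditions, not the
behaviour of the method on arbitrary real diaries.

## Problem sizes and reproducibility

Defaults used throughout tests and the acceptance script, chosen as the
study-emulation conditions: 62 subjects × mode-84 days for estimation
checks (≈ 1,450–1,700 design rows after the 56-day burn-in); 200 × 200
panels for the correlogram span (band ≈ 0.012); 50 replicate panels for
coefficient recovery; 20 for R²; 1,000 null replicates for test
calibration.  Every random quantity descends from a single integer
seed; repeated runs are byte-identical.

## Known limitations

* Inference at active order constraints is approximate (no polyhedral
  adjustment); the affected tail coefficients are reported with their
  activity flags.
* df bookkeeping is package-specific (documented above) and not
  comparable across SEM software.
* The multilevel path inherits MixedLM's boundary behaviour; variances
  at the boundary are flagged, not tested formally.
* The ICC is the one-way random-effects form with the unbalanced-k₀
  correction, computed on raw counts by default (a transformed-scale
  flag exists); no two-way or agreement ICCs.
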