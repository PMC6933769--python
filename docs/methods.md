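# Methods

## Model and estimation

The package estimates a factor-augmented VAR in which both the observation
loadings and the VAR coefficients drift as Gaussian random walks:

- observation: `x_{i,t} = z_t' λ_{i,t} + v_{i,t}`, `v_{i,t} ~ N(0, V_{i,t})`,
  with `z_t = (Y_t, F_t)` — the growth series first, then `l` common
  factors;
- state VAR(p): `z_t = C_t + Σ_j B_{t,j} z_{t-j} + ε_t`, `ε_t ~ N(0, Q_t)`;
- parameter drift: `λ_t = λ_{t-1} + innovation`, `β_t = β_{t-1} + innovation`.

Exact likelihood treatment of the drift covariances is replaced by the
standard approximate scheme for this model family:

1. **Initialization.** Zero-mean diffuse priors with diagonal covariance
   `init_state_variance · I` on `λ_0` and `β_0`; `V_0 = I_n` and
   `Q_0 = I_{l+1}` (identity scale 1 by convention).
2. **Prediction with forgetting.** Means carry over; covariances inflate by
   `1/k₃` (loadings) and `1/k₄` (coefficients). This is algebraically the
   random-walk prediction with innovation covariances
   `W_t = (k₃⁻¹ − 1) Σ^λ_{t-1|t-1}` and `R_t = (k₄⁻¹ − 1) Σ^β_{t-1|t-1}`.
   (A sign convention note: the subtraction must run this way round —
   `(1 − k⁻¹)Σ` would be negative definite for `k < 1` and contradicts the
   defining property that `k = 1` gives `W = R = 0` exactly.)
3. **EWMA covariances.** `V̂_{i,t} = k₁ V_{i,t-1} + (1−k₁) μ̂²_{i,t}` with
   `μ̂_{i,t}` the one-step prediction residual of equation `i`, and
   `Q̂_t = k₂ Q_{t-1} + (1−k₂) ε̂_t ε̂_t'` with `ε̂_t` the VAR prediction
   residual. Residuals use the *predicted* (not updated) parameter means.
   `Q̂` is symmetrized after every step.
4. **Measurement update.** The loading filter runs per equation with a
   scalar observation (so `V_t` is diagonal throughout, matching the
   per-equation EWMA). The coefficient filter runs on the stacked state
   `vec(B_t)` with observation matrix `I_{l+1} ⊗ w_t'`,
   `w_t = (1, z_{t-1}, …, z_{t-p})`, and a single shared covariance
   `Σ^β` of dimension `(1 + (l+1)p)(l+1)`. The two filters are interleaved
   per time step, loadings first; the first `p` quarters serve only as
   initial conditions for the coefficient filter.
5. **Smoothing.** Fixed-interval (Rauch–Tung–Striebel) backward recursion
   for `λ` and `β` with gain `C_t = Σ_{t|t} Σ_{t+1|t}⁻¹` (pseudo-inverse
   fallback with a logged warning if the predicted covariance is singular).
   `V` and `Q` are smoothed by the inverse-weighted (harmonic) recursion
   `M_{t|T}⁻¹ = k · M_{t|t}⁻¹ + (1−k) · M_{t+1|T}⁻¹` with the matching decay
   factor; the printed source for this recursion is typographically
   ambiguous, and the harmonic form was chosen because it preserves
   positive definiteness and reduces to the filtered path at `k = 1`.

With `k₃ = k₄ = 1` the filter is exact conjugate Bayesian (recursive least
squares) regression on a constant-parameter model, and the test suite pins
both the filtered and the smoothed paths to independently coded
conjugate-regression and RTS oracles at 1e-6.

A modelling note: the observation equation is sometimes written with
loadings on the factors only; the estimation algorithm regresses each
indicator on the full `z_t = (Y_t, F_t)`. The implementation follows the
algorithm — loadings are on growth and factors jointly.

### Defaults and what they mean

| parameter | default | meaning |
|---|---|---|
| `k1`, `k2` | 0.96 | EWMA decay for `V_t`, `Q_t`; ≈ 25-quarter effective memory |
| `k3`, `k4` | 0.99 | forgetting for `λ_t`, `β_t`; 1 = constant parameters |
| `lags` (p) | 2 | VAR lag order (quarterly data) |
| `n_factors` (l) | 3 | principal-component factors |
| `init_state_variance` | 10 | diffuse prior scale on `λ_0`, `β_0` |
| `init_V_scale`, `init_Q_scale` | 1 | `V_0`, `Q_0` identity scales |

`k1 = k2 = 0.96` and `k3 = k4 = 0.99` are the established defaults for
forgetting-factor TVP-VAR estimation; the source analysis states no values.
`l = 3`, `p = 2` are desk-scale choices, overridable everywhere.

## Factors

Full-sample principal components of the standardized indicator block
(growth excluded), scores rescaled to unit sample variance, computed once
(two-step estimation; no recursive re-estimation). Each factor's sign is
fixed so that its largest-magnitude loading is positive. This rule makes
repeated runs and impulse responses reproducibly oriented; it cannot
distinguish a panel from its global negation (loadings are quadratic in the
data), so score paths of `X` and `−X` agree only up to one global sign.
Factor-number selection criteria are out of scope.

## Impulse responses

"Local" time-varying IRFs: at each origin `t` the smoothed `B_t`, `Q_t` and
`λ_t` are frozen; the horizon-`h` state response is the top block of the
`h`-th companion-matrix power applied to the structural impact vector, and
the indicator response is `λ_{i,t}` applied to the state response.
Identification is recursive with ordering `(F_1..F_l, Y)` — growth last, so
the growth shock is orthogonalized against contemporaneous factor
innovations; the ordering is configurable. Default horizon: 12 quarters.
An unstable companion matrix (spectral radius ≥ 1) is flagged with a
warning but responses are still returned. No confidence bands are produced.

## DCC-GARCH pre-test

Standard two-stage Gaussian QMLE: GARCH(1,1) per margin
(`h_t = ω + α r²_{t-1} + β h_{t-1}`, `h_0` = sample variance), then
DCC(1,1) on the standardized residuals
(`Q_t = (1−a−b)S + a e_{t-1}e_{t-1}' + b Q_{t-1}`, `Q_1 = S`). Both stages
use bounded L-BFGS-B from a fixed five-point grid of starting values, with
a penalty keeping `α+β` and `a+b` inside the stationarity region (boundary
estimates are pulled to the interior with a warning). Which health series
enters the bivariate pair is a user choice: any single indicator, or
(opt-in) the first principal component of the health block.

Identification caveat: under a no-ARCH null (`α → 0`) the GARCH `β` is not
identified — every `(ω, β)` with `ω/(1−β)` equal to the sample variance
fits equally well — so only `α` and the implied unconditional variance are
meaningful there.

## Preprocessing protocol

Per series, in order: annual→quarterly interpolation, log transform of
flagged level series, additive seasonal adjustment, unit-root screen with
first differencing, standardization (sample sd, `T−1` denominator).

- **Interpolation.** Piecewise-quadratic, one polynomial per year,
  constrained so each year's four quarterly values average exactly to the
  annual value (the requirement that keeps annual totals of rates and
  levels intact), with continuity of value and slope at year boundaries
  and natural (zero-curvature) end conditions.
- **Seasonal adjustment.** Additive quarterly-dummy centering: subtract
  each quarter's mean deviation from the overall mean. Deterministic,
  mean-preserving, idempotent. This is a deliberately simple adjustment —
  no ARIMA-model-based seasonal extraction, no trading-day or outlier
  handling.
- **Unit-root screen.** Augmented Dickey–Fuller regression with neither
  constant nor trend, fixed augmentation order 4 (one year of quarterly
  lags), 5% critical value. The panel screen requires a series to pass on
  both its raw and its demeaned scale ("both" variant): the raw
  no-constant test treats any series fluctuating around a nonzero level as
  nonstationary (the intended growth-rate semantics for logged levels),
  while the demeaned test is what the standardized output must satisfy —
  demeaning alone makes random walks pass the −1.95 critical value too
  often to serve as the sole screen. Because differencing shortens a
  series, the screen is iterated on the shrinking common quarterly window
  until every retained column passes; one difference is the default cap,
  with drop / second-difference / keep as configurable fallbacks (the
  growth series is always kept).
- **Standardization** happens last, on the final common window, so output
  columns are exactly mean-0/sd-1.

Every applied step is recorded per series in a transform log.

## Synthetic data

`simulate_tvp_favar` draws exactly from the model above, recording the full
`λ_t`, `β_t`, `F_t`, `V_t`, `Q_t` paths as ground truth. Initial VAR
coefficients are rescaled so the companion spectral radius is ≤ 0.95
(scaling lag-`j` blocks by `c^j` scales every companion eigenvalue by `c`);
random-walk coefficient steps are rejection-sampled to keep the radius
below 0.97, since an unconstrained walk exits the stationarity region
almost surely at meaningful innovation scales and the panel then explodes.
After repeated rejections a step is skipped. This truncation is part of the
data-generating process the recovery tests evaluate.

`simulate_raw_panel` emulates a 74-dimensional quarterly 2005–2017 panel:
one growth series (AR(1), unconditional mean 9.31, sd 2.48), nine annual
health indicators whose latent quarterly processes are calibrated to
published per-series means and standard deviations and partially driven by
the growth series (coupling weight 0.4, a moderate co-movement chosen once
for realism), and ≥ 60 macro series with a three-factor structure, a
unit-root subset, a deterministically seasonal subset, and a positive
log-flagged subset. Annual health values are the means of their four latent
quarters, so the interpolation stage has a recoverable truth. The generator
reproduces first and second moments and a factor structure — not actual
macro dynamics (crisis timing, policy shifts), so passing tests demonstrate
correctness of the estimation machinery, not empirical conclusions about
any real economy.

`simulate_regime_correlation` produces the DCC fixture: GARCH(1,1) margins
with piecewise-constant innovation correlation (default −0.8 for the first
half, +0.8 for the second, T = 400).

## Numerical choices

- Covariances symmetrized after every update; PSD is validated in tests at
  eigenvalue tolerance −1e-10.
- Singular innovation variances raise with a diagnostic; singular predicted
  covariances in the smoother fall back to the pseudo-inverse with a
  warning.
- All simulation randomness flows through `numpy.random.default_rng(seed)`;
  estimation itself is deterministic.
- The pipeline's run manifest hashes the scientific configuration
  (filesystem paths excluded) so reruns are comparable across directories.

## Problem sizes used in the test suite

Oracle-equivalence checks run at `n = 2, l = 1, T = 10`; impulse-response
closed-form checks over 100 random stable VAR(p ≤ 3) systems; recovery
experiments at `n = 20, l = 2, T = 200` (drifting coefficients, 20 seeds)
and `T ∈ {100, 400}` (constant coefficients); the DCC regime test at
`T = 400` over 20 seeds; the end-to-end pipeline at the default 74-series,
52-quarter configuration. These sizes make the full suite complete in a
few minutes on a single core while leaving the stochastic assertions
comfortable margins.

## Known limitations

- No stochastic volatility, MCMC, or model averaging over forgetting
  factors; uncertainty is summarized only by filter covariances.
- The forgetting/EWMA scheme is an approximation to the exact random-walk
  state space; its accuracy degrades when true innovation covariances are
  far from proportional to the state covariance.
- PCA identifies individual factors only up to rotation when factor
  variances are close; downstream IRFs are invariant to this rotation only
  through the loadings.
- The quarterly-dummy seasonal adjustment removes stable additive
  seasonality only.
- The no-constant ADF rule has low power in small samples; at ~50 quarters
  some stationary-but-persistent series are differenced and some marginal
  series are dropped by the screen.
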