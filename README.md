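# tvpfavar

A Python toolkit for studying how macroeconomic growth shocks propagate to
population-health indicators when the transmission itself changes over time.
It implements a **time-varying-parameter factor-augmented VAR (TVP-FAVAR)**
estimated by forgetting-factor Kalman filtering, time-varying impulse
responses to a growth shock, a **DCC-GARCH** dynamic-correlation pre-test,
and the mixed-frequency data-preparation protocol such analyses need
(annual-to-quarterly disaggregation, seasonal adjustment, unit-root
screening, standardization). A synthetic-data generator with recorded ground
truth makes every stage testable without any external dataset.

It is aimed at epidemiologists and health economists working with a small
set of health outcome series (mortality and morbidity rates, medical
expenditure) alongside a high-dimensional block of quarterly macro
indicators.

## Model

Observed indicators load on a low-dimensional state with time-varying
loadings,

```
x_{i,t} = z_t' λ_{i,t} + v_{i,t},          v_{i,t} ~ N(0, V_{i,t}),
```

where `z_t = (Y_t, F_t)` stacks the growth series `Y_t` and `l` common
factors `F_t` (full-sample principal components of the standardized panel).
The state follows a VAR(p) with drifting coefficients,

```
z_t = C_t + B_{t,1} z_{t-1} + ... + B_{t,p} z_{t-p} + ε_t,   ε_t ~ N(0, Q_t),
```

and both `λ_t` and `β_t = (C_t, B_{t,1..p})` evolve as Gaussian random
walks. Estimation is a single forward pass of a forgetting-factor Kalman
filter — predicted state covariances are inflated by `1/k₃` (loadings) and
`1/k₄` (coefficients), while `V_t` and `Q_t` follow EWMA recursions with
decay `k₁`, `k₂` — followed by a fixed-interval backward smoother. Setting
`k₃ = k₄ = 1` makes the implied state-innovation covariances exactly zero
and recovers constant-parameter recursive least squares.

Impulse responses of each health indicator to a one-standard-deviation
growth shock are computed per origin date with coefficients frozen at their
smoothed values, identified recursively (Cholesky, growth ordered last).
The DCC-GARCH pre-test fits GARCH(1,1) margins and a DCC(1,1) correlation
recursion to a growth/health pair, giving a time-varying correlation path
that motivates (or not) the time-varying model.

## Worked example

```python
import numpy as np
import tvpfavar as tf

# simulate from the data-generating process with drifting VAR coefficients
cfg = tf.DgpConfig(n_obs_series=20, n_factors=2, lags=2, T=200,
                   coef_innovation_sd=0.05, seed=1)
panel, truth = tf.simulate_tvp_favar(cfg)

model = tf.TVPFAVAR(n_factors=2, lags=2).fit(panel.X, panel.Y)
print(f"max |W_hat| over the pass: {model.max_abs_W_hat_:.4f}")

surface = model.irf_surface(horizon=12, targets=["x00"])
print(f"IRF of x00 at origin t=100, horizons 0..4: "
      f"{np.round(surface.values[100, :5, 0], 4)}")

pair, rho_true = tf.simulate_regime_correlation(tf.RegimeCorrConfig(seed=0))
result = tf.dynamic_correlation(pair[:, 0], pair[:, 1])
print(f"DCC(1,1): a={result.a:.3f}, b={result.b:.3f}")
print(f"mean correlation, first half: {result.rho_path[:200].mean():+.3f}, "
      f"second half: {result.rho_path[200:].mean():+.3f}")
```

Output:

```
max |W_hat| over the pass: 0.1017
IRF of x00 at origin t=100, horizons 0..4: [-0.1836  0.5323  0.4765 -0.1019  0.2105]
DCC(1,1): a=0.089, b=0.906
mean correlation, first half: -0.681, second half: +0.674
```

The first line is the largest implied state-innovation covariance entry at
the default forgetting factors (0.99); with `k3=1.0, k4=1.0` it is exactly
0. The IRF row gives the response of indicator `x00` (in standardized
units) to a one-sd growth shock at quarter 100. The DCC fit on a fixture
whose true conditional correlation switches from −0.8 to +0.8 mid-sample
recovers persistent correlation dynamics (`a + b ≈ 0.995`) and the sign
switch in the half-sample means.

## Command-line pipeline

```bash
tvpfavar all --outdir run --seed 7          # simulate → preprocess → fit → IRF → DCC → report
tvpfavar simulate --outdir run --seed 7     # stages are also runnable one at a time
tvpfavar preprocess --outdir run
```

`all` writes the raw panel (`panel.csv`, `meta.csv`), the standardized
panel with its transform log, factor scores/loadings, the filtered and
smoothed state archive, the impulse-response surface, the DCC correlation
path, per-indicator figures, a sub-period sign summary, and a JSON run
manifest. Runs are bit-reproducible given the same config and seed.

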