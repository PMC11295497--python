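# ivair

Instrumental-variable estimation of the short-term effect of fine
particulate matter (PM2.5) on daily cause-specific cardiovascular mortality.

## The problem

Daily time-series studies of air pollution and mortality conventionally fit
a covariate-adjusted Poisson regression (a GAM with splines of time,
temperature and co-pollutants). Such models only adjust for *measured*
confounders; anything unmeasured that moves with both pollution and deaths
biases the estimate, typically toward the null. Two meteorological
variables offer a way out: **boundary-layer height (BLH)** — the vertical
mixing depth of the atmosphere — and **wind speed (WS)** dilute and disperse
locally emitted pollution but have no plausible direct pathway to daily
cardiovascular deaths. They can serve as *instrumental variables* (IVs):
correlated with exposure, independent of unobserved confounders, and
affecting the outcome only through exposure.

`ivair` implements the full IV pipeline for daily count data:

1. **Detrending.** The exposure (2-day mean PM2.5, lags 0–1) is regressed on
   natural cubic splines of the day index (df 52) and temperature (df 15)
   plus day-of-week dummies; the residual ε₁ is the exposure used downstream,
   free of trend, season and temperature:
   ε₁ = pmₜ − (β₀ + ns(time, 52) + ns(temₜ, 15) + dow).
2. **First stage.** A radial-kernel support-vector regression combines lag-0
   and lag-1 BLH and WS into a single pollution-calibrated instrument:
   ε₁ = f(BLHₜ, WSₜ) + ε₂, giving ε̂₁ = Ê[ε₁ | IV] (clean of confounding)
   and the residual ε₂ (a confounder surrogate).
3. **Second stage**, Poisson log-link regressions of daily counts:
   - **2SPS** (two-stage predictor substitution):
     log E[yₜ] = β₃ + β₄·ε̂₁ + ns(time, 32);
   - **CFN** (control function):
     log E[yₜ] = β₅ + β₆·pmₜ + ns(ε₂, 17) + ns(time, 32);
   - **GAM** comparator:
     log E[yₜ] = β₀ + DOW + β₇·pmₜ + ns(tem, 15) + ns(time, 32) + ns(O₃, 23).
   Effects are reported as excess risk, ER = (e^{10β} − 1)·100 (% per
   10 µg/m³).
4. **Inference.** Block-bootstrap percentile confidence intervals (whole
   pipeline refit per replicate, preserving serial correlation) and a
   **negative-control exposure** test: the same SVR calibration applied to
   *post-outcome* BLH/WS yields an exposure ε̂₁′ that cannot cause past
   deaths; a significant coefficient on it flags residual confounding.

A synthetic daily-series generator with known ground truth (configurable
true ER, seasonality, autocorrelated meteorology, an unobserved
time-structured confounder that biases non-IV estimators) makes every stage
testable without any external data.

## Worked example

```python
from ivair import PMMortalityIV, SyntheticConfig, generate_dataset

data, truth = generate_dataset(SyntheticConfig(seed=1))   # 5 years, true ER 1.0%/10ug
res = PMMortalityIV(data, causes=("cvd",)).fit()
res.negative_control(causes=("cvd",))
print(res.summary())
```

```
Instrumental-variable PM2.5 mortality model
============================================================
n days analysed: 1825
detrend variance explained: 0.6914
first stage (SVR) remaining variance explained: 0.2531
corr(eps1_hat, tem) = -0.030   corr(eps1_hat, time) = -0.014
------------------------------------------------------------
method cause  ER%/10ug             95% CI        p
2SPS   cvd       -0.37      (-3.32, 2.68)    0.812
CFN    cvd       -0.43      (-2.97, 2.17)    0.743
GAM    cvd       -0.75      (-2.11, 0.63)    0.285
negative control [cvd]: coef=-0.00367 p=0.274 -> pass
```

Reading this: time, season and temperature explain 69% of exposure
variance; the instruments recover 25% of what remains; the calibrated
instrument is clean of temperature (r = −0.03) and trend; the negative
control passes. The point estimates are far from the true 1.0% because a
*single* five-year city series is genuinely noisy at these effect sizes
(the Wald CI spans roughly ±3 ER points). The estimators' operating
characteristics emerge across replicates — from the same machinery:

```python
from ivair.studies import recovery_study
recovery_study(n_replicates=100, seed=1)["mean_er"]
# {'2SPS': 0.871, 'CFN': 0.799, 'GAM': 0.563}   (truth: 1.0)
```

Under an active unobserved confounder the conventional GAM is attenuated by
half while the IV estimators stay near the truth — the core argument for
instrumenting.

Command line:

```bash
ivair simulate --n-days 1826 --seed 1 --out daily.csv
ivair descriptives daily.csv
ivair run daily.csv --causes cvd --out report/ --seed 1
```

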