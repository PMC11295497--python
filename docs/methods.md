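# Methods

## Model and identification

The estimand is the short-term (acute) effect of PM2.5 on daily
cause-specific cardiovascular mortality: the log-rate slope β per µg/m³ of
the 2-day mean exposure (lags 0 and 1), reported as excess risk
ER = (e^{10β} − 1)·100, the % change per 10 µg/m³.

Identification rests on the classical IV assumptions for boundary-layer
height and wind speed: *correlation* (they physically dilute locally emitted
pollution), *independence* (weather realisations are not driven by whatever
unmeasured factors move daily deaths), and *exclusion* (no direct pathway
from mixing height or ordinary wind to cardiovascular death on the same
day). None of the three is testable directly; the negative-control exposure
test probes their joint plausibility.

All series — exposure, instruments, outcome — share strong seasonality and
temperature dependence, so the analysis first removes that common structure
from the exposure by OLS on natural cubic splines of the day index and of
temperature plus day-of-week dummies (treatment coding, Monday reference).
The residual ε₁ is the working exposure. The instruments are residualized
against the same design before entering the first stage; otherwise the
calibrated instrument ε̂₁ = Ê[ε₁ | BLH, WS] would inherit the instruments'
own temperature correlation (about −0.25 at this generator's couplings)
instead of the near-zero value a valid calibration should show. With
residualized instruments the fitted ε̂₁–temperature correlation is ≈ −0.03.

The first stage is an ε-insensitive support-vector regression with a radial
kernel on lag-0/lag-1 BLH and WS (z-scored). Fitted values are in-sample.
The decomposition ε₁ = ε̂₁ + ε₂ is exact by construction; ε̂₁ is the
substituted predictor for 2SPS, ε₂ the confounder surrogate for the control
function (entering through its own natural spline so it may act
nonlinearly).

For a *linear* model with a linear first stage, predictor substitution and
the control function coincide exactly with two-stage least squares (the test
suite verifies this to 1e−8). For the Poisson log link they differ; both are
consistent for small effects under the IV assumptions, while the GAM
comparator remains biased by whatever confounding it cannot measure.

## Degrees of freedom and tunables

| parameter | default | role |
|---|---|---|
| df time (detrend) | 52 | ~10.4/year over 5 years; absorbs trend + season |
| df temperature (detrend) | 15 | smooth temperature–PM2.5 response |
| df time (second stage) | 32 | seasonal control in the outcome model |
| df ε₂ (CFN) | 17 | nonlinear confounder surrogate |
| df temperature / ozone (GAM) | 15 / 23 | measured-confounder adjustment |
| SVR C / tube / kernel scale | 1 / 0.1·sd(ε₁) / 1/(p·var) | reproducible defaults; block-CV tuner optional |
| IV lags / negative-control leads | (0, 1) / (1, 2) | days before/after the outcome day |

Degrees of freedom are fixed-df regression splines (no penalized smoothing);
`select_df_cv` offers a deterministic GCV criterion (n·RSS/(n−p)²) and a
contiguous-block 10-fold option for choosing them from data. SVR
hyperparameter defaults are deliberately fixed rather than auto-tuned so a
run is reproducible from its config alone; `tune_svr` does 5-fold
contiguous-block CV over a small (C, tube) grid when asked.

The weak-instrument flag uses the *linear* first-stage R² (< 5% flags), not
the in-sample SVR fraction, because a flexible learner can "explain" several
percent of pure noise in-sample.

## Inference

Percentile block-bootstrap confidence intervals: the analysis frame (with
all lagged covariates materialised per row) is resampled in whole contiguous
blocks — non-overlapping fixed blocks by default, moving blocks optionally —
concatenated to the original length, and the entire pipeline (detrend,
first stage, second stage) is refit per replicate, so first-stage
uncertainty propagates. Default block length: the smallest lag at which the
outcome-residual autocorrelation drops below 2/√n, capped at 60 days. A
second-stage-only mode holds the first-stage decomposition fixed for speed.
Replicate failures are tolerated up to 10%, then inference aborts. Below
200 replicates the percentile CI is reported with a warning. When the
bootstrap is not run, Wald intervals from the GLM are attached.

The negative-control exposure applies the identical calibration machinery to
instruments measured 1–2 days *after* the outcome day (trailing rows dropped
symmetrically with the lag handling). Post-outcome weather cannot cause past
deaths, so in a Poisson fit containing both ε̂₁ and ε̂₁′ the negative
coefficient should be null; p > 0.05 is the pipeline-level pass.

## The synthetic generator

The generator emulates a five-year (n = 1826 days) daily series for a
heavily polluted northern-Chinese city, anchored to published descriptive
statistics of such a setting: temperature 289.8 ± ~10 K with an annual
sinusoid; lognormal boundary-layer height (median 118 m, strong right skew)
coupled positively to temperature; wind speed ~2.5 ± 1 m/s coupled
positively to log-BLH; PM2.5 ~112 µg/m³ with a winter peak, negative
loadings on temperature, BLH and WS, and Gaussian noise; summer-peaking
ozone generated causally inert; Poisson counts for five causes (means ≈
CVD 41, IHD 22, MI 18, CVA 12, HTN 1) with winter-peaking log-rate
seasonality (amplitude 0.15) and small day-of-week effects. The realized
Spearman structure reproduces the signs and rough magnitudes observed in
such data: tem–PM ≈ −0.75, BLH–PM and WS–PM negative, tem–BLH and BLH–WS
positive.

The causal knobs: `true_beta` (default ln(1.01)/10, i.e. ER 1.0% per
10 µg/m³, applied to the 2-day mean exposure; day 1 uses lag 0 only) and an
unobserved confounder U — AR(1) with standard-normal marginal
(autocorrelation 0.6) — loading on PM2.5 with κ = 4 µg/m³ per SD and on the
log death rate with γ = −0.005 per SD. U is time-structured on purpose: a
white-noise confounder would be removed almost entirely by detrending,
making the IV exercise trivial. The signs make the conventional GAM
*under*-estimate the effect (upward-confounded exposure, downward-confounded
outcome), the direction IV analyses in this literature are motivated by.
U is independent of BLH/WS by construction, so the IV independence
assumption holds exactly in the generator; a deliberate violation (wiring U
into future weather) is how the negative-control power examples are built.

Under these defaults the detrending stage explains ~65–70% of exposure
variance and the instruments ~25–33% of the remainder; the per-replicate
sampling SD of a single study's ER estimate is ≈ 1.3–1.5 ER points (so a
lone five-year series is individually noisy at a true ER of 1%). Across 100
replicates the mean 2SPS and CFN ERs land near 1.0 while the GAM mean is
attenuated to ≈ 0.5.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: spatial exposure heterogeneity (no land-use
regression surface; exposure is a single city-level series), measurement
error in exposure, overdispersion (optional gamma-mixing is available but
off by default, as daily counts of this size are close to Poisson),
multi-day distributed lags beyond the 2-day mean, harvesting/mortality
displacement, co-pollutant confounding beyond the single ozone term, and
real meteorology's full dependence structure (fronts, persistence regimes).

## Numerical choices and degenerate inputs

- Natural cubic splines follow the R `ns` convention: boundary knots at
  min/max, df−1 interior knots at equally spaced quantiles, exactly df
  columns, linear extrapolation beyond the boundaries. A df=1 basis is a
  linear function, which is what makes the linear control-function oracle
  exact.
- Variance-explained fractions on a zero-variance response are defined as 0;
  a constant exposure detrends to identically zero residuals.
- A zero-variance calibrated instrument raises an unidentified-exposure
  error; a degenerate (constant) ε₂ drops the surrogate spline rather than
  failing the CFN fit.
- Quantiles everywhere use the linear-interpolation definition.
- The Poisson GLM is plain maximum likelihood (IRLS via statsmodels); a
  Pearson-dispersion diagnostic is attached to every estimate but never used
  to rescale inference.
- Time is the 1-based row position of the analysis frame (identical to the
  day index on original data; well-defined on bootstrap-resampled frames).
- The first max(lag) rows are dropped once, so all estimators see identical
  rows; negative-control fits drop max(lead) trailing rows symmetrically.
- All randomness flows from one seed through named `SeedSequence` substreams
  (per weather component, per cause, per study replicate), so components are
  independently reproducible and replicate seeds stay below 2³¹.

## Known limitations

- In-sample SVR fitted values leak a small amount of endogenous variation
  into ε̂₁ (measured correlation with the confounder ≈ 0.02 at n = 1826),
  giving 2SPS a mild upward finite-sample bias (~ +0.15 ER points under
  default conditions). An out-of-fold first stage would remove it at the
  cost of extra variance; in-sample fitting is the field's usual practice
  and the default here.
- Percentile (not BCa) bootstrap intervals; no stationary/geometric-block
  bootstrap; no analytic sandwich SEs as primary output.
- The SVR tube-width monotonicity ("wider tube explains less") holds only up
  to O(1e−3) jitter; it is a trend, not a theorem.
- CI coverage of the full-pipeline block bootstrap is not separately
  simulated in the test suite (cost); null coverage is verified for the
  Wald intervals, and bootstrap SEs are validated against the analytic
  long-run variance of an AR(1) mean.
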