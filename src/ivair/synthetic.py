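"""Synthetic daily mortality / air-pollution series with known ground truth.

The generator emulates the statistical structure of a multi-year daily
time-series study of PM2.5 and cardiovascular mortality in a northern-Chinese
city: strong seasonality in temperature and mortality (winter-peaking
deaths), PM2.5 that rises in cold weather (strongly negative temperature
dependence), boundary-layer height (BLH) and wind speed (WS) that disperse
pollution (negative loadings on PM2.5), autocorrelated meteorology, Poisson
death counts with day-of-week effects, a configurable true exposure effect,
and an unobserved time-structured confounder ``U`` that biases any estimator
that cannot adjust for it.

Causal structure (the premise of the IV design built in by construction):

* ``U`` is independent of BLH and WS, so instrument-driven variation in
  PM2.5 is clean of confounding;
* ``U`` loads on PM2.5 with weight ``confounder_to_pm`` (kappa) and on the
  log death rate with weight ``confounder_to_deaths`` (gamma);
* deaths respond to the 2-day mean (lag 0 / lag 1) of PM2.5 with log-rate
  slope ``true_beta`` per ug/m3.

Default magnitudes are anchored to the descriptive statistics of the
Binzhou 2016-2020 study setting (mean daily temperature ~289.8 K, WS
~2.47 m/s, BLH ~185 m, PM2.5 ~111.6 ug/m3, daily deaths CVD ~41, IHD ~22,
MI ~18, CVA ~12, HTN ~1) and to its correlation sign structure
(Spearman tem-PM strongly negative, BLH-PM and WS-PM mildly negative,
tem-BLH positive, BLH-WS positive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionError

__all__ = [
    "CAUSES",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_confounder",
    "generate_weather",
    "generate_pm25",
    "generate_ozone",
    "generate_deaths",
    "generate_dataset",
]

#: Cause-of-death columns produced by the generator, in output order.
CAUSES = ("cvd", "ihd", "mi", "cva", "htn")

_DAYS_PER_YEAR = 365.25
_TEMP_PEAK_DOY = 198  # mid-July temperature maximum


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic daily-series generator.

    All standard deviations are *stationary* (marginal) SDs of the AR(1)
    noise components; AR coefficients must lie strictly inside (-1, 1).
    """

    n_days: int = 1826  # five calendar years, 2016-2020
    seed: int = 0
    start_date: str = "2016-01-01"

    # outcome model
    baseline_log_rate: float = math.log(41.05)  # log mean daily CVD deaths
    cause_means: dict[str, float] = field(
        default_factory=lambda: {"cvd": 41.05, "ihd": 21.59, "mi": 18.10, "cva": 12.35, "htn": 1.06}
    )
    true_beta: float = math.log(1.01) / 10.0  # 1.0% excess risk per 10 ug/m3
    mortality_seasonal_amplitude: float = 0.15  # log scale, winter peak
    dow_effects: tuple[float, ...] = (0.0, 0.01, 0.01, 0.0, 0.01, -0.02, -0.03)
    overdispersion: float = 0.0  # gamma-mixture variance inflation; 0 = pure Poisson

    # unobserved confounder U (AR(1), standard-normal marginal by default)
    confounder_sd: float = 1.0
    confounder_ar: float = 0.6
    confounder_to_pm: float = 4.0  # kappa, ug/m3 per SD of U
    confounder_to_deaths: float = -0.005  # gamma, log-rate per SD of U

    # temperature (K)
    temp_mean_K: float = 289.8
    temp_amplitude_K: float = 12.0
    temp_ar: float = 0.8
    temp_noise_sd: float = 3.0

    # boundary-layer height (m): lognormal (real BLH is strongly right-skewed),
    # with temperature entering on the log scale
    blh_median: float = 118.0
    blh_mean: float = 177.0  # centring constant for the PM2.5 loading
    blh_temp_coupling: float = 0.031  # log-m per K of temperature deviation
    blh_ar: float = 0.7
    blh_noise_sd: float = 0.9  # stationary SD of log-BLH noise
    blh_floor: float = 5.0

    # wind speed (m/s); coupled positively to (log) BLH
    ws_mean: float = 2.47
    ws_blh_coupling: float = 0.58  # m/s per unit of log-BLH deviation
    ws_ar: float = 0.5
    ws_noise_sd: float = 0.8
    ws_floor: float = 0.1

    # PM2.5 (ug/m3)
    pm_mean: float = 111.63
    pm_seasonal_amplitude: float = 5.0  # winter peak
    pm_temp_loading: float = -0.35  # ug/m3 per K
    iv_strength: tuple[float, float] = (-0.016, -1.2)  # loadings on BLH (per m) and WS (per m/s)
    pm_noise_sd: float = 4.5
    pm_floor: float = 1.0

    # ozone (ug/m3); summer-peaking, causally inert by default
    ozone_mean: float = 60.0
    ozone_seasonal_amplitude: float = 25.0
    ozone_ar: float = 0.6
    ozone_noise_sd: float = 8.0
    ozone_floor: float = 1.0

    def __post_init__(self) -> None:
        if self.n_days < 60:
            raise ConfigurationError(f"n_days must be >= 60, got {self.n_days}")
        for name in (
            "confounder_sd", "temp_noise_sd", "blh_noise_sd", "ws_noise_sd",
            "pm_noise_sd", "ozone_noise_sd", "overdispersion",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in ("confounder_ar", "temp_ar", "blh_ar", "ws_ar", "ozone_ar"):
            if not abs(getattr(self, name)) < 1:
                raise ConfigurationError(f"|{name}| must be < 1, got {getattr(self, name)}")
        if len(self.dow_effects) != 7:
            raise ConfigurationError(
                f"dow_effects must have exactly 7 entries, got {len(self.dow_effects)}"
            )
        unknown = set(self.cause_means) - set(CAUSES)
        if unknown:
            raise ConfigurationError(f"cause_means has unknown causes: {sorted(unknown)}")

    @property
    def true_er_per_10(self) -> float:
        """Ground-truth excess risk (%) per 10 ug/m3, derived from true_beta."""
        return (math.exp(10.0 * self.true_beta) - 1.0) * 100.0

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_date, periods=self.n_days, freq="D")

    def _streams(self) -> dict[str, np.random.Generator]:
        names = ["confounder", "temp", "blh", "ws", "pm", "ozone", *(f"deaths_{c}" for c in CAUSES)]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(s) for n, s in zip(names, children)}


@dataclass
class SyntheticTruth:
    """Ground-truth record returned with each generated dataset."""

    config: SyntheticConfig
    true_er_per_10: float
    realized_confounder: np.ndarray

    def to_json(self, path: str | Path) -> None:
        payload = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "true_er_per_10": self.true_er_per_10,
            "realized_confounder": [float(u) for u in self.realized_confounder],
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _ar1(rng: np.random.Generator, n: int, phi: float, stationary_sd: float) -> np.ndarray:
    """AR(1) noise with the given stationary SD, initialised at stationarity."""
    if stationary_sd == 0:
        return np.zeros(n)
    innov_sd = stationary_sd * math.sqrt(1.0 - phi * phi)
    e = rng.normal(0.0, 1.0, n)
    out = np.empty(n)
    out[0] = stationary_sd * e[0]
    for t in range(1, n):
        out[t] = phi * out[t - 1] + innov_sd * e[t]
    return out


def _winter(dates: pd.DatetimeIndex) -> np.ndarray:
    """Seasonal shape peaking in mid-January (= negative of the summer peak)."""
    doy = dates.day_of_year.to_numpy(dtype=float)
    return -np.cos(2.0 * np.pi * (doy - _TEMP_PEAK_DOY) / _DAYS_PER_YEAR)


def generate_confounder(config: SyntheticConfig) -> np.ndarray:
    """Unobserved confounder U: AR(1) with standard-normal marginal by default.

    U is time-structured on purpose: a white-noise confounder would be removed
    almost entirely by the detrending stage, making the IV exercise trivial.
    """
    rng = config._streams()["confounder"]
    return _ar1(rng, config.n_days, config.confounder_ar, config.confounder_sd)


def generate_weather(config: SyntheticConfig) -> pd.DataFrame:
    """Daily temperature (K), boundary-layer height (m) and wind speed (m/s).

    Temperature = annual sinusoid + AR(1) noise.  BLH is lognormal with
    temperature entering on the log scale (positive coupling), reproducing
    the strong right skew of observed mixing heights; WS is positively
    coupled to log-BLH.  BLH and WS are floored at small positive values
    near observed minima (rarely binding).
    """
    streams = config._streams()
    dates = config.dates()
    season = -_winter(dates)  # summer peak
    tem = config.temp_mean_K + config.temp_amplitude_K * season + _ar1(
        streams["temp"], config.n_days, config.temp_ar, config.temp_noise_sd
    )
    tem_dev = tem - config.temp_mean_K
    log_blh_dev = config.blh_temp_coupling * tem_dev + _ar1(
        streams["blh"], config.n_days, config.blh_ar, config.blh_noise_sd
    )
    blh = np.maximum(config.blh_median * np.exp(log_blh_dev), config.blh_floor)
    ws = config.ws_mean + config.ws_blh_coupling * log_blh_dev + _ar1(
        streams["ws"], config.n_days, config.ws_ar, config.ws_noise_sd
    )
    ws = np.maximum(ws, config.ws_floor)
    return pd.DataFrame({"tem": tem, "blh": blh, "ws": ws}, index=dates)


def generate_pm25(weather: pd.DataFrame, U: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Daily PM2.5 (ug/m3).

    Winter-peaking seasonal term, negative linear loadings on BLH, WS and
    temperature, plus ``kappa * U`` and Gaussian noise; floored at a small
    positive value.
    """
    U = np.asarray(U, dtype=float)
    if len(weather) != config.n_days or U.size != config.n_days:
        raise DimensionError(
            f"weather ({len(weather)}) and U ({U.size}) must both have length n_days={config.n_days}"
        )
    rng = config._streams()["pm"]
    winter = _winter(pd.DatetimeIndex(weather.index))
    b_blh, b_ws = config.iv_strength
    pm = (
        config.pm_mean
        + config.pm_seasonal_amplitude * winter
        + config.pm_temp_loading * (weather["tem"].to_numpy() - config.temp_mean_K)
        + b_blh * (weather["blh"].to_numpy() - config.blh_mean)
        + b_ws * (weather["ws"].to_numpy() - config.ws_mean)
        + config.confounder_to_pm * U
        + rng.normal(0.0, config.pm_noise_sd, config.n_days)
    )
    return np.maximum(pm, config.pm_floor)


def generate_ozone(config: SyntheticConfig) -> np.ndarray:
    """Daily ozone (ug/m3): summer-peaking seasonal series, independent of deaths."""
    rng = config._streams()["ozone"]
    season = -_winter(config.dates())
    o3 = config.ozone_mean + config.ozone_seasonal_amplitude * season + _ar1(
        rng, config.n_days, config.ozone_ar, config.ozone_noise_sd
    )
    return np.maximum(o3, config.ozone_floor)


def two_day_mean(pm: np.ndarray) -> np.ndarray:
    """Mean of lag-0 and lag-1 PM2.5; the first day uses lag 0 only."""
    pm = np.asarray(pm, dtype=float)
    out = pm.copy()
    out[1:] = 0.5 * (pm[1:] + pm[:-1])
    return out


def generate_deaths(
    pm: np.ndarray, U: np.ndarray, weather: pd.DataFrame, config: SyntheticConfig
) -> pd.DataFrame:
    """Cause-specific daily death counts.

    ``deaths_t ~ Poisson(mu_t)`` with
    ``log mu_t = log(cause mean) + seasonal + dow + true_beta * (x2_t - pm_mean)
    + gamma * U_t`` where ``x2`` is the 2-day mean exposure (day 1 uses lag 0
    only).  Cause series are independent draws sharing the same covariates.
    With ``overdispersion = d > 0`` the rate is gamma-mixed so that
    ``Var = mu * (1 + d * mu)``.
    """
    pm = np.asarray(pm, dtype=float)
    U = np.asarray(U, dtype=float)
    if pm.size != config.n_days or U.size != config.n_days or len(weather) != config.n_days:
        raise DimensionError("pm, U and weather must all have length n_days")
    dates = config.dates()
    winter = _winter(dates)
    dow = dates.dayofweek.to_numpy()
    dow_term = np.asarray(config.dow_effects, dtype=float)[dow]
    x2 = two_day_mean(pm)
    shared = (
        config.mortality_seasonal_amplitude * winter
        + dow_term
        + config.true_beta * (x2 - config.pm_mean)
        + config.confounder_to_deaths * U
    )
    if not np.all(np.isfinite(shared)):
        raise FloatingPointError("non-finite log death rate encountered during generation")
    streams = config._streams()
    counts = {}
    for cause in CAUSES:
        mean_c = config.cause_means.get(cause)
        if mean_c is None:
            continue
        if cause == "cvd":
            # honour an explicit baseline override for the headline cause
            log_mu = config.baseline_log_rate + shared
        else:
            log_mu = math.log(mean_c) + shared
        mu = np.exp(log_mu)
        rng = streams[f"deaths_{cause}"]
        if config.overdispersion > 0:
            shape = 1.0 / config.overdispersion
            mu = rng.gamma(shape, mu / shape)
        counts[f"deaths_{cause}"] = rng.poisson(mu)
    return pd.DataFrame(counts, index=dates)


def generate_dataset(
    config: SyntheticConfig, path: str | Path | None = None
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Assemble the full daily series and its ground-truth record.

    Returns a DataFrame with columns ``date, deaths_cvd, deaths_ihd,
    deaths_mi, deaths_cva, deaths_htn, pm25, tem, ws, blh, ozone`` and a
    :class:`SyntheticTruth`.  If ``path`` is given the table is written as CSV
    (ISO-8601 dates) with the truth record in a ``<path>.truth.json`` sidecar.
    """
    U = generate_confounder(config)
    weather = generate_weather(config)
    pm = generate_pm25(weather, U, config)
    ozone = generate_ozone(config)
    deaths = generate_deaths(pm, U, weather, config)
    df = pd.DataFrame({"date": config.dates()})
    for c in deaths.columns:
        df[c] = deaths[c].to_numpy()
    df["pm25"] = pm
    df["tem"] = weather["tem"].to_numpy()
    df["ws"] = weather["ws"].to_numpy()
    df["blh"] = weather["blh"].to_numpy()
    df["ozone"] = ozone
    truth = SyntheticTruth(config=config, true_er_per_10=config.true_er_per_10, realized_confounder=U)
    if path is not None:
        path = Path(path)
        try:
            out = df.copy()
            out["date"] = out["date"].dt.strftime("%Y-%m-%d")
            out.to_csv(path, index=False)
            truth.to_json(path.with_suffix(path.suffix + ".truth.json"))
        except OSError as exc:
            raise OSError(f"failed to write synthetic dataset to {path}: {exc}") from exc
    return df, truth
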