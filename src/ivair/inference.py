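"""Resampling inference and design-validity checks.

Daily mortality and meteorology are serially correlated, so ordinary
bootstrap resampling of single days understates uncertainty.  The block
bootstrap here resamples contiguous blocks of days with replacement
(non-overlapping fixed blocks by default, moving blocks optionally),
concatenates them to the original length, re-runs the requested estimator on
each replicate, and reports the percentile interval of the excess risk.
Re-running the *entire* pipeline (detrend, first stage, second stage) inside
each replicate propagates first-stage uncertainty; a fast second-stage-only
mode exists for comparison.

The negative-control exposure test applies the same SVR calibration to
instruments measured *after* the outcome day.  Post-outcome weather cannot
cause past deaths, so a significant coefficient on this negative exposure
signals residual confounding or model failure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError, DimensionError, InferenceError
from .first_stage import IVFeatureSpec, fit_first_stage
from .splines import SplineSpec, natural_spline_basis

__all__ = [
    "BootstrapSpec",
    "NegativeControlResult",
    "default_block_length",
    "block_bootstrap",
    "block_bootstrap_ci",
    "build_negative_exposure",
    "negative_control_test",
    "spearman_matrix",
    "summary_stats",
]


@dataclass(frozen=True)
class BootstrapSpec:
    """Block-bootstrap settings.

    ``block_length=None`` means: choose the smallest lag at which the sample
    autocorrelation of the estimator's outcome residuals drops below
    ``2/sqrt(n)`` (capped at 60 days) -- the point past which serial
    dependence is statistically negligible.
    """

    n_replicates: int = 1000
    block_length: int | None = None
    seed: int = 0
    ci_level: float = 0.95
    scheme: str = "fixed"  # "fixed" non-overlapping blocks or "moving" blocks

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be positive")
        if self.block_length is not None and self.block_length < 1:
            raise ConfigurationError("block_length must be positive")
        if not 0 < self.ci_level < 1:
            raise ConfigurationError("ci_level must be in (0, 1)")
        if self.scheme not in ("fixed", "moving"):
            raise ConfigurationError(f"unknown bootstrap scheme {self.scheme!r}")


def default_block_length(residuals: np.ndarray, cap: int = 60) -> int:
    """Smallest lag with |sample autocorrelation| below ``2/sqrt(n)``, capped."""
    x = np.asarray(residuals, dtype=float)
    x = x - x.mean()
    n = x.size
    denom = float(np.dot(x, x))
    if denom == 0:
        return 1
    threshold = 2.0 / np.sqrt(n)
    for lag in range(1, min(cap, n - 1) + 1):
        acf = float(np.dot(x[:-lag], x[lag:])) / denom
        if abs(acf) < threshold:
            return lag
    return cap


def _block_indices(n: int, spec: BootstrapSpec, L: int, rng: np.random.Generator) -> np.ndarray:
    if L >= n // 2:
        raise ConfigurationError(f"block_length {L} must be < n/2 = {n // 2}")
    if spec.scheme == "fixed":
        starts_pool = np.arange(0, n - L + 1, L)  # non-overlapping partition blocks
    else:
        starts_pool = np.arange(0, n - L + 1)  # moving blocks
    n_blocks = int(np.ceil(n / L))
    starts = rng.choice(starts_pool, size=n_blocks, replace=True)
    idx = (starts[:, None] + np.arange(L)[None, :]).ravel()
    return idx[:n]


def block_bootstrap(
    frame: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    spec: BootstrapSpec,
    block_length: int | None = None,
) -> np.ndarray:
    """Replicate values of ``estimator`` over block-resampled frames.

    The estimator receives a frame of the original length whose rows are
    resampled whole blocks (row order inside blocks preserved); any lagged
    covariates must already be materialised as columns so each row carries
    its own history.  Replicates where the estimator raises are recorded as
    NaN; more than 10% failures raises :class:`InferenceError`.
    """
    n = len(frame)
    L = block_length if block_length is not None else (spec.block_length or default_block_length(
        frame.iloc[:, 0].to_numpy()))
    rng = np.random.default_rng(spec.seed)
    values = np.empty(spec.n_replicates)
    failures = 0
    for r in range(spec.n_replicates):
        idx = _block_indices(n, spec, L, rng)
        boot = frame.iloc[idx].reset_index(drop=True)
        try:
            values[r] = estimator(boot)
        except Exception:
            values[r] = np.nan
            failures += 1
    if failures > 0.1 * spec.n_replicates:
        raise InferenceError(
            f"{failures}/{spec.n_replicates} bootstrap replicates failed to fit"
        )
    return values


def block_bootstrap_ci(
    frame: pd.DataFrame,
    estimator: Callable[[pd.DataFrame], float],
    spec: BootstrapSpec,
    block_length: int | None = None,
) -> tuple[float, float, float]:
    """Percentile confidence interval and bootstrap SE of an estimator.

    Deterministic given ``spec.seed``.  Returns ``(ci_low, ci_high, se)``.
    """
    if spec.n_replicates < 200:
        warnings.warn(
            f"n_replicates={spec.n_replicates} < 200; percentile CI will be noisy",
            stacklevel=2,
        )
    values = block_bootstrap(frame, estimator, spec, block_length=block_length)
    values = values[np.isfinite(values)]
    alpha = 1.0 - spec.ci_level
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi), float(values.std(ddof=1))


@dataclass
class NegativeControlResult:
    """Outcome of the negative-control exposure test for one cause."""

    cause: str
    coef_negative: float
    se_negative: float
    p_value: float
    coef_exposure_with_negative: float
    coef_exposure_without_negative: float
    leads: tuple[int, ...]
    passed: bool  # p > 0.05: no detectable residual confounding

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["leads"] = list(self.leads)
        return d


def build_negative_exposure(
    series: pd.DataFrame,
    epsilon1: np.ndarray,
    kept: np.ndarray,
    leads: tuple[int, ...] = (1, 2),
    hyperparameters: dict | None = None,
    design: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Instrument-predicted exposure from *post-outcome* BLH/WS.

    Applies the same SVR machinery as the first stage, but with instrument
    values ``leads`` days after the outcome day.  ``design`` (the detrending
    design matrix aligned to ``kept``) is projected off the lead features
    first, mirroring the treatment of the lagged instruments.  Returns
    ``(epsilon1_prime, kept_nc)`` where ``kept_nc`` indexes the rows of
    ``series`` (a subset of ``kept``) for which all leads exist; trailing
    rows are dropped symmetrically with the lag handling at the start.
    """
    if not leads:
        raise ConfigurationError("lead list must be nonempty")
    if any(l < 1 for l in leads):
        raise ConfigurationError(f"leads must be positive, got {leads}")
    n = len(series)
    max_lead = max(leads)
    if n <= max_lead + kept.min():
        raise DimensionError("series too short for requested leads")
    keep_mask = kept <= n - 1 - max_lead
    kept_nc = kept[keep_mask]
    cols = []
    for v in ("blh", "ws"):
        x = series[v].to_numpy(dtype=float)
        for l in leads:
            cols.append(x[kept_nc + l])
    F = np.column_stack(cols)
    if design is not None:
        D = design[keep_mask]
        coef, *_ = np.linalg.lstsq(D, F, rcond=None)
        F = F - D @ coef
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    fs = fit_first_stage(
        np.asarray(epsilon1)[keep_mask], F, hyperparameters=hyperparameters,
        feature_spec=IVFeatureSpec(lags=tuple(sorted(leads))),
    )
    return fs.epsilon1_hat, kept_nc


def negative_control_test(
    y: np.ndarray,
    epsilon1_hat: np.ndarray,
    epsilon1_prime: np.ndarray,
    time_index: np.ndarray,
    cause: str = "cvd",
    df_time: int = 32,
    leads: tuple[int, ...] = (1, 2),
) -> NegativeControlResult:
    """Poisson fit with both the calibrated and the negative exposure.

    ``log E[y] = b0 + b_iv * epsilon1_hat + b_nc * epsilon1_prime +
    ns(time, df)``.  A pipeline-level pass is ``p > 0.05`` on ``b_nc``.
    """
    from .effects import fit_poisson_glm

    y = np.asarray(y, dtype=float)
    if not (y.size == len(epsilon1_hat) == len(epsilon1_prime) == len(time_index)):
        raise DimensionError("negative-control vectors are not aligned")
    tspl = natural_spline_basis(np.asarray(time_index, float), SplineSpec(df_time))
    X_full = np.column_stack([np.ones(y.size), epsilon1_hat, epsilon1_prime, tspl])
    coef, cov, _ = fit_poisson_glm(y, X_full)
    se_nc = float(np.sqrt(cov[2, 2]))
    z = coef[2] / se_nc if se_nc > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    X_red = np.column_stack([np.ones(y.size), epsilon1_hat, tspl])
    coef_red, _, _ = fit_poisson_glm(y, X_red)
    return NegativeControlResult(
        cause=cause, coef_negative=float(coef[2]), se_negative=se_nc, p_value=p,
        coef_exposure_with_negative=float(coef[1]),
        coef_exposure_without_negative=float(coef_red[1]),
        leads=tuple(leads), passed=bool(p > 0.05),
    )


def spearman_matrix(series: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Pairwise Spearman rank correlations (symmetric, unit diagonal).

    Pairs involving a constant column are flagged as NaN.
    """
    if len(series) < 3:
        raise DimensionError("need at least 3 rows for rank correlations")
    k = len(variables)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            a = series[variables[i]].to_numpy(dtype=float)
            b = series[variables[j]].to_numpy(dtype=float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(a, b).statistic
            out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=variables, columns=variables)


def summary_stats(series: pd.DataFrame, variables: list[str] | None = None) -> pd.DataFrame:
    """Descriptive table: mean, SD, P25, median, P75, min, max per variable.

    Quantiles use the linear-interpolation definition so P25/P75 are
    reproducible across tools.
    """
    if len(series) == 0:
        raise DimensionError("empty series")
    if variables is None:
        variables = [c for c in series.columns if c not in ("date", "dow")]
    rows = {}
    for v in variables:
        x = series[v].to_numpy(dtype=float)
        rows[v] = {
            "mean": x.mean(),
            "sd": x.std(ddof=1) if x.size > 1 else 0.0,
            "p25": np.quantile(x, 0.25),
            "median": np.quantile(x, 0.5),
            "p75": np.quantile(x, 0.75),
            "min": x.min(),
            "max": x.max(),
        }
    return pd.DataFrame(rows).T[["mean", "sd", "p25", "median", "p75", "min", "max"]]
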