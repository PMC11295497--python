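"""Model/Results interface tying the pipeline stages together.

:class:`PMMortalityIV` is built from a validated daily series and exposes
``fit()``, which runs detrending and the SVR first stage once and then the
three second-stage estimators (2SPS, CFN, GAM) for each requested cause of
death.  The returned :class:`IVResults` carries the estimates with their
uncertainties, a ``summary()`` table, block-bootstrap confidence intervals
and the negative-control exposure test.

Design conventions:

* the exposure is the 2-day mean of PM2.5 (lag 0 and lag 1), matching the
  convention of acute air-pollution mortality studies;
* the first ``max(lag)`` rows are dropped so every estimator sees identical
  rows; the time spline uses the 1-based row position of the analysis frame;
* all lagged instrument columns are materialised on the analysis frame, so
  block-bootstrap resampling keeps each day's own history.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .detrend import DetrendFit, detrend_pm
from .effects import EffectEstimate, fit_2sps, fit_cfn, fit_gam
from .exceptions import ConfigurationError
from .first_stage import (
    FirstStageFit,
    IVFeatureSpec,
    first_stage_diagnostics,
    fit_first_stage,
    tune_svr,
)
from .inference import (
    BootstrapSpec,
    NegativeControlResult,
    block_bootstrap_ci,
    build_negative_exposure,
    default_block_length,
    negative_control_test,
)
from .synthetic import CAUSES

__all__ = ["PMMortalityIV", "IVResults"]

METHODS = ("2SPS", "CFN", "GAM")


@dataclass(frozen=True)
class _Params:
    causes: tuple[str, ...] = CAUSES
    exposure_lags: tuple[int, ...] = (0, 1)
    iv_lags: tuple[int, ...] = (0, 1)
    df_time_detrend: int = 52
    df_tem_detrend: int = 15
    df_time: int = 32
    df_eps2: int = 17
    df_tem: int = 15
    df_ozone: int = 23
    svr: dict | str | None = None  # None = defaults, dict = explicit, "tune" = block-CV tuner
    detrend_instruments: bool = True

    def __post_init__(self) -> None:
        unknown = [c for c in self.causes if c not in CAUSES]
        if unknown:
            raise ConfigurationError(f"unknown causes: {unknown}")
        if not self.exposure_lags or min(self.exposure_lags) < 0:
            raise ConfigurationError("exposure_lags must be nonnegative and nonempty")


class PMMortalityIV:
    """Instrumental-variable model of daily PM2.5 and cause-specific mortality.

    Parameters
    ----------
    data : DataFrame
        Daily series with columns ``date, deaths_<cause>..., pm25, tem, ws,
        blh, ozone``; validated on construction.
    causes : sequence of str
        Causes to analyse, subset of ``("cvd", "ihd", "mi", "cva", "htn")``.
    svr : dict | "tune" | None
        SVR hyperparameters for the first stage (``C``, ``epsilon``,
        ``gamma``), the string ``"tune"`` for the contiguous-block CV tuner,
        or None for the reproducible defaults.

    Examples
    --------
    >>> from ivair import PMMortalityIV, SyntheticConfig, generate_dataset
    >>> data, truth = generate_dataset(SyntheticConfig(seed=1))
    >>> res = PMMortalityIV(data, causes=("cvd",)).fit()
    >>> print(res.summary())  # doctest: +SKIP
    """

    def __init__(self, data: pd.DataFrame, causes=CAUSES, **params) -> None:
        self.series = _io.validate_daily_series(data)
        self.params = _Params(causes=tuple(causes), **params)
        self.frame, self.kept = _build_frame(self.series, self.params)

    @classmethod
    def from_csv(cls, path: str | Path, column_map: dict | None = None, **kwargs) -> "PMMortalityIV":
        return cls(_io.read_daily_series(path, column_map=column_map), **kwargs)

    def fit(self, methods: tuple[str, ...] = METHODS) -> "IVResults":
        """Run detrending, the first stage and all requested second stages."""
        detrend_fit, fs_fit = _fit_stages(self.frame, self.params)
        estimates: dict[tuple[str, str], EffectEstimate] = {}
        failures: dict[tuple[str, str], str] = {}
        for cause in self.params.causes:
            y = self.frame[f"deaths_{cause}"].to_numpy()
            for method in methods:
                try:
                    estimates[(method, cause)] = _second_stage(
                        method, cause, y, self.frame, detrend_fit, fs_fit, self.params
                    )
                except Exception as exc:
                    failures[(method, cause)] = f"{type(exc).__name__}: {exc}"
        diagnostics = first_stage_diagnostics(fs_fit, self.series, self.kept)
        return IVResults(self, detrend_fit, fs_fit, diagnostics, estimates, failures)


def _build_frame(series: pd.DataFrame, params: _Params) -> tuple[pd.DataFrame, np.ndarray]:
    n = len(series)
    pm = series["pm25"].to_numpy(dtype=float)
    start = max(max(params.exposure_lags), max(params.iv_lags))
    kept = np.arange(start, n)
    x = np.mean([pm[kept - l] for l in params.exposure_lags], axis=0)
    frame = pd.DataFrame({
        "day_index": kept + 1,
        "x": x,
        "tem": series["tem"].to_numpy()[kept],
        "ozone": series["ozone"].to_numpy()[kept],
        "dow": series["dow"].to_numpy()[kept],
    })
    for v in ("blh", "ws"):
        col = series[v].to_numpy(dtype=float)
        for l in params.iv_lags:
            frame[f"{v}_lag{l}"] = col[kept - l]
    for cause in CAUSES:
        col = f"deaths_{cause}"
        if col in series.columns:
            frame[col] = series[col].to_numpy()[kept]
    return frame, kept


def _fit_stages(frame: pd.DataFrame, params: _Params) -> tuple[DetrendFit, FirstStageFit]:
    from .splines import SplineSpec

    t = np.arange(1, len(frame) + 1, dtype=float)
    detrend_fit = detrend_pm(
        frame, SplineSpec(params.df_time_detrend), SplineSpec(params.df_tem_detrend),
        exposure=frame["x"].to_numpy(), time_index=t,
    )
    spec = IVFeatureSpec(lags=tuple(params.iv_lags))
    F = frame[[f"{v}_lag{l}" for v in spec.variables for l in spec.lags]].to_numpy(dtype=float)
    if params.detrend_instruments:
        # instruments share the exposure's seasonal/temperature structure;
        # remove it so the calibrated instrument is clean of both
        F = detrend_fit.residualize(F)
    F = (F - F.mean(axis=0)) / F.std(axis=0)
    hp = params.svr
    if hp == "tune":
        hp = tune_svr(detrend_fit.epsilon1, F)
    fs_fit = fit_first_stage(detrend_fit.epsilon1, F, hyperparameters=hp, feature_spec=spec)
    return detrend_fit, fs_fit


def _second_stage(
    method: str, cause: str, y: np.ndarray, frame: pd.DataFrame,
    detrend_fit: DetrendFit, fs_fit: FirstStageFit, params: _Params,
) -> EffectEstimate:
    t = np.arange(1, len(frame) + 1, dtype=float)
    if method == "2SPS":
        return fit_2sps(y, fs_fit, t, cause=cause, df_time=params.df_time)
    if method == "CFN":
        return fit_cfn(y, frame["x"].to_numpy(), fs_fit, t, cause=cause,
                       df_time=params.df_time, df_eps2=params.df_eps2)
    if method == "GAM":
        return fit_gam(y, frame["x"].to_numpy(), frame["tem"].to_numpy(),
                       frame["ozone"].to_numpy(), frame["dow"].to_numpy(), t,
                       cause=cause, df_time=params.df_time, df_tem=params.df_tem,
                       df_ozone=params.df_ozone)
    raise ConfigurationError(f"unknown method {method!r}")


class IVResults:
    """Fitted results: estimates, diagnostics, bootstrap and negative control."""

    def __init__(self, model: PMMortalityIV, detrend_fit: DetrendFit,
                 first_stage_fit: FirstStageFit, diagnostics: dict,
                 estimates: dict, failures: dict) -> None:
        self.model = model
        self.detrend_fit = detrend_fit
        self.first_stage_fit = first_stage_fit
        self.diagnostics = diagnostics
        self.estimates = estimates
        self.failures = failures
        self.negative_controls: dict[str, NegativeControlResult] = {}

    # ------------------------------------------------------------------ views
    def estimates_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (method, cause)."""
        rows = [est.to_dict() for est in self.estimates.values()]
        for (method, cause), msg in self.failures.items():
            rows.append({"method": method, "cause": cause, "error": msg})
        df = pd.DataFrame(rows)
        order = {m: i for i, m in enumerate(METHODS)}
        return df.sort_values(
            ["cause", "method"], key=lambda s: s.map(order).fillna(s)
        ).reset_index(drop=True)

    def summary(self) -> str:
        """Human-readable summary in the spirit of statsmodels results."""
        lines = [
            "Instrumental-variable PM2.5 mortality model",
            "=" * 60,
            f"n days analysed: {len(self.model.frame)}",
            f"detrend variance explained: {self.detrend_fit.fraction_variance_explained:.4f}",
            "first stage (SVR) remaining variance explained: "
            f"{self.first_stage_fit.fraction_remaining_variance_explained:.4f}",
            f"corr(eps1_hat, tem) = {self.diagnostics['corr_eps1hat_tem']:+.3f}   "
            f"corr(eps1_hat, time) = {self.diagnostics['corr_eps1hat_time']:+.3f}",
        ]
        if self.diagnostics["weak_instrument"]:
            lines.append("WARNING: weak instrument (first stage explains < 5%)")
        lines.append("-" * 60)
        lines.append(f"{'method':<6} {'cause':<5} {'ER%/10ug':>9} {'95% CI':>18} {'p':>8}")
        for (method, cause), est in sorted(self.estimates.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            ci = f"({est.ci_low:.2f}, {est.ci_high:.2f})"
            lines.append(
                f"{method:<6} {cause:<5} {est.er_per_10:>9.2f} {ci:>18} {est.p_value:>8.3f}"
            )
        for (method, cause), msg in self.failures.items():
            lines.append(f"{method:<6} {cause:<5} FAILED: {msg}")
        for cause, nc in self.negative_controls.items():
            verdict = "pass" if nc.passed else "FAIL"
            lines.append(
                f"negative control [{cause}]: coef={nc.coef_negative:+.5f} "
                f"p={nc.p_value:.3f} -> {verdict}"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------- inference
    def bootstrap_ci(
        self,
        spec: BootstrapSpec,
        methods: tuple[str, ...] | None = None,
        causes: tuple[str, ...] | None = None,
        mode: str = "full",
    ) -> dict[tuple[str, str], EffectEstimate]:
        """Replace Wald CIs with block-bootstrap percentile CIs.

        ``mode='full'`` refits detrending + first stage + second stage inside
        every replicate (propagating first-stage uncertainty);
        ``mode='second-stage'`` holds the first-stage decomposition fixed and
        refits only the outcome regression.  Updated estimates are stored in
        ``self.estimates`` and returned.
        """
        if mode not in ("full", "second-stage"):
            raise ConfigurationError(f"unknown bootstrap mode {mode!r}")
        methods = methods or tuple({m for m, _ in self.estimates})
        causes = causes or self.model.params.causes
        params = self.model.params
        frame = self.model.frame.copy()
        if mode == "second-stage":
            frame["eps1_hat"] = self.first_stage_fit.epsilon1_hat
            frame["eps2"] = self.first_stage_fit.epsilon2
        updated = {}
        for cause in causes:
            for method in methods:
                key = (method, cause)
                if key not in self.estimates:
                    continue
                point = self.estimates[key]
                L = spec.block_length or default_block_length(point.deviance_residuals)

                def estimator(boot: pd.DataFrame, _m=method, _c=cause) -> float:
                    y = boot[f"deaths_{_c}"].to_numpy()
                    if mode == "full":
                        dfit, ffit = _fit_stages(boot, params)
                    else:
                        dfit, ffit = None, _FixedFirstStage(
                            boot["eps1_hat"].to_numpy(), boot["eps2"].to_numpy()
                        )
                    return _second_stage(_m, _c, y, boot, dfit, ffit, params).er_per_10

                lo, hi, se = block_bootstrap_ci(frame, estimator, spec, block_length=L)
                est = dc_replace(
                    point, ci_low=lo, ci_high=hi, ci_kind="block-bootstrap",
                    deviance_residuals=point.deviance_residuals,
                )
                est.bootstrap_se = se
                est.block_length = L
                self.estimates[key] = est
                updated[key] = est
        return updated

    def negative_control(
        self, leads: tuple[int, ...] = (1, 2), causes: tuple[str, ...] | None = None
    ) -> dict[str, NegativeControlResult]:
        """Negative-control exposure test using post-outcome instruments."""
        causes = causes or self.model.params.causes
        series = self.model.series
        kept = self.model.kept
        hp = None
        if self.first_stage_fit.method == "svr":
            hp = {k: v for k, v in self.first_stage_fit.hyperparameters.items()
                  if k in ("C", "epsilon", "gamma")}
        eps1_prime, kept_nc = build_negative_exposure(
            series, self.detrend_fit.epsilon1, kept, leads=leads, hyperparameters=hp,
            design=self.detrend_fit.design if self.model.params.detrend_instruments else None,
        )
        m_nc = len(kept_nc)
        t = np.arange(1, m_nc + 1, dtype=float)
        out = {}
        for cause in causes:
            y = self.model.frame[f"deaths_{cause}"].to_numpy()[:m_nc]
            out[cause] = negative_control_test(
                y, self.first_stage_fit.epsilon1_hat[:m_nc], eps1_prime, t,
                cause=cause, df_time=self.model.params.df_time, leads=leads,
            )
        self.negative_controls.update(out)
        return out


class _FixedFirstStage:
    """Stand-in first stage carrying precomputed columns through a bootstrap."""

    method = "fixed"
    hyperparameters: dict = {}

    def __init__(self, eps1_hat: np.ndarray, eps2: np.ndarray) -> None:
        self.epsilon1_hat = eps1_hat
        self.epsilon2 = eps2
        self.epsilon1 = eps1_hat + eps2
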