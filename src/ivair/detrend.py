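"""Exposure detrending: removing time, temperature and day-of-week structure.

PM2.5, BLH and WS all share strong seasonal and temperature-driven variation,
so the instrumented analysis works with the *detrended* exposure: the
residual of an ordinary least-squares regression of PM2.5 on natural cubic
splines of the day index and of temperature plus day-of-week dummies
(treatment coding, Monday reference).  That residual is independent of
long-term trends, season and temperature by construction and serves as the
exposure variable everywhere downstream.

Default degrees of freedom (52 for time over a five-year series, 15 for
temperature) follow common practice for daily mortality series; a
generalized cross-validation selector and a contiguous-block k-fold option
are provided for choosing them from data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import RankDeficiencyError, SelectionError
from .splines import SplineSpec, natural_spline_basis

__all__ = ["DetrendFit", "dow_dummies", "build_detrend_design", "detrend_pm", "select_df_cv"]


def dow_dummies(dow: np.ndarray) -> np.ndarray:
    """Six treatment-coded day-of-week dummies with Monday (0) as reference."""
    dow = np.asarray(dow, dtype=int)
    out = np.zeros((dow.size, 6))
    for j in range(1, 7):
        out[:, j - 1] = dow == j
    return out


@dataclass
class DetrendFit:
    """Artifacts of the exposure-detrending regression.

    ``epsilon1`` is the residual exposure (ug/m3), mean zero and orthogonal
    to every fitted design column by the least-squares normal equations.
    """

    spec_time: SplineSpec
    spec_tem: SplineSpec
    beta0: float
    coefficients: np.ndarray
    epsilon1: np.ndarray
    fraction_variance_explained: float
    fitted: np.ndarray
    design: np.ndarray | None = None

    def residualize(self, columns: np.ndarray) -> np.ndarray:
        """Project other columns off this fit's design (same adjustment set).

        Used to remove time/temperature/day-of-week structure from the
        instrument columns before the first stage, so the calibrated
        instrument cannot inherit temperature or trend correlation.
        """
        if self.design is None:
            raise ValueError("DetrendFit carries no design matrix")
        coef, *_ = np.linalg.lstsq(self.design, columns, rcond=None)
        return columns - self.design @ coef

    def to_dict(self) -> dict:
        return {
            "df_time": self.spec_time.df,
            "df_tem": self.spec_tem.df,
            "beta0": self.beta0,
            "fraction_variance_explained": self.fraction_variance_explained,
        }


def build_detrend_design(
    time_index: np.ndarray, tem: np.ndarray, dow: np.ndarray,
    spec_time: SplineSpec, spec_tem: SplineSpec,
) -> np.ndarray:
    """Design matrix [1 | ns(time) | ns(tem) | dow dummies]."""
    return np.column_stack([
        np.ones(len(time_index)),
        natural_spline_basis(np.asarray(time_index, dtype=float), spec_time),
        natural_spline_basis(np.asarray(tem, dtype=float), spec_tem),
        dow_dummies(dow),
    ])


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify offending columns by pivoted QR diagnostics
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * diag.max()).tolist()
        raise RankDeficiencyError(
            f"detrending design is rank deficient (rank {rank} of {X.shape[1]}; "
            f"suspect columns {bad})"
        )
    return coef, X @ coef


def detrend_pm(
    series: pd.DataFrame,
    spec_time: SplineSpec = SplineSpec(52),
    spec_tem: SplineSpec = SplineSpec(15),
    exposure: np.ndarray | None = None,
    time_index: np.ndarray | None = None,
) -> DetrendFit:
    """OLS of the exposure on splines of time and temperature plus DOW dummies.

    Parameters
    ----------
    series : DataFrame
        Validated daily series (needs ``tem`` and ``dow`` columns; ``pm25``
        if ``exposure`` is not given).
    exposure : array, optional
        Exposure vector to detrend; defaults to ``series['pm25']``.  The
        pipeline passes the 2-day mean exposure here.
    time_index : array, optional
        Day index for the time spline; defaults to 1-based row order.
    """
    y = np.asarray(series["pm25"] if exposure is None else exposure, dtype=float)
    n = y.size
    t = np.arange(1, n + 1, dtype=float) if time_index is None else np.asarray(time_index, float)
    X = build_detrend_design(t, series["tem"].to_numpy(), series["dow"].to_numpy(),
                             spec_time, spec_tem)
    coef, fitted = _ols(X, y)
    eps1 = y - fitted
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    frac = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(eps1**2)) / ss_tot
    return DetrendFit(
        spec_time=spec_time, spec_tem=spec_tem, beta0=float(coef[0]),
        coefficients=coef, epsilon1=eps1, fraction_variance_explained=frac,
        fitted=fitted, design=X,
    )


def select_df_cv(
    series: pd.DataFrame,
    candidate_dfs: list[tuple[int, int]],
    method: str = "gcv",
    k: int = 10,
    exposure: np.ndarray | None = None,
) -> tuple[int, int]:
    """Choose (df_time, df_tem) for the detrending model by cross-validation.

    ``method='gcv'`` (default) minimises the generalized cross-validation
    score ``n * RSS / (n - p)^2`` of the linear detrending model, a
    deterministic leave-one-out surrogate.  ``method='kfold'`` uses k
    contiguous blocks (time-series-aware folds) and minimises out-of-block
    mean squared error.
    """
    if not candidate_dfs:
        raise SelectionError("candidate df grid is empty")
    y = np.asarray(series["pm25"] if exposure is None else exposure, dtype=float)
    n = y.size
    t = np.arange(1, n + 1, dtype=float)
    tem = series["tem"].to_numpy()
    dow = series["dow"].to_numpy()

    best, best_score = None, np.inf
    n_failed = 0
    for df_time, df_tem in candidate_dfs:
        try:
            X = build_detrend_design(t, tem, dow, SplineSpec(df_time), SplineSpec(df_tem))
            p = X.shape[1]
            if p >= n:
                raise RankDeficiencyError("more columns than observations")
            if method == "gcv":
                _, fitted = _ols(X, y)
                rss = float(np.sum((y - fitted) ** 2))
                score = n * rss / (n - p) ** 2
            elif method == "kfold":
                bounds = np.linspace(0, n, k + 1, dtype=int)
                sse, m = 0.0, 0
                for a, b in zip(bounds[:-1], bounds[1:]):
                    mask = np.ones(n, dtype=bool)
                    mask[a:b] = False
                    coef, _, rank, _ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
                    if rank < p:
                        raise RankDeficiencyError("rank-deficient training fold")
                    pred = X[~mask] @ coef
                    sse += float(np.sum((y[~mask] - pred) ** 2))
                    m += b - a
                score = sse / m
            else:
                raise SelectionError(f"unknown selection method {method!r}")
        except RankDeficiencyError:
            n_failed += 1
            continue
        if score < best_score:
            best, best_score = (df_time, df_tem), score
    if best is None:
        raise SelectionError(
            f"all {n_failed} candidate df pairs produced rank-deficient fits"
        )
    return best
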