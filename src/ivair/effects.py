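"""Second-stage effect estimators: 2SPS, control function, and the GAM comparator.

All three model daily cause-specific death counts with a Poisson log-link
regression and report the excess risk (ER) per 10 ug/m3 of PM2.5,
``ER = (exp(10 * beta) - 1) * 100``:

* **2SPS** (two-stage predictor substitution): counts on the calibrated
  instrument ``epsilon1_hat`` plus a natural spline of time (df 32).  The
  substituted predictor is clean of unobserved confounding by construction.
* **CFN** (control function): counts on the raw 2-day-mean PM2.5, a natural
  spline of the first-stage residual ``epsilon2`` (df 17, the confounder
  surrogate, allowed to act nonlinearly) and a spline of time (df 32).
* **GAM** comparator: the conventional covariate-adjusted regression --
  counts on 2-day-mean PM2.5, day-of-week dummies and splines of
  temperature (df 15), time (df 32) and ozone (df 23).  It adjusts only for
  *measured* confounders and is the benchmark the IV estimators are
  compared against.

Confidence intervals attached here are Wald intervals from the GLM; the
block-bootstrap machinery in :mod:`ivair.inference` replaces them with
percentile intervals that propagate first-stage uncertainty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .detrend import dow_dummies
from .exceptions import DegenerateDataError, FitConvergenceError, RankDeficiencyError
from .first_stage import FirstStageFit
from .splines import SplineSpec, natural_spline_basis

__all__ = [
    "EffectEstimate",
    "er_per_10",
    "beta_from_er",
    "fit_poisson_glm",
    "fit_2sps",
    "fit_cfn",
    "fit_gam",
]


def er_per_10(beta: float) -> float:
    """Excess risk (%) per 10 ug/m3: ``(exp(10*beta) - 1) * 100``."""
    return (math.exp(10.0 * beta) - 1.0) * 100.0


def beta_from_er(er: float) -> float:
    """Inverse of :func:`er_per_10`: ``ln(1 + er/100) / 10``."""
    return math.log1p(er / 100.0) / 10.0


@dataclass
class EffectEstimate:
    """One estimator's result for one cause of death."""

    method: str  # "2SPS" | "CFN" | "GAM"
    cause: str
    beta: float  # log-rate slope per ug/m3
    se_beta: float
    er_per_10: float
    ci_low: float  # ER scale, %
    ci_high: float
    p_value: float
    ci_kind: str = "wald"
    dfs: dict = field(default_factory=dict)
    n_obs: int = 0
    deviance_residuals: np.ndarray | None = None
    dispersion: float = float("nan")  # quasi-likelihood diagnostic only

    def to_dict(self) -> dict:
        return {
            "method": self.method, "cause": self.cause,
            "beta": self.beta, "se_beta": self.se_beta,
            "er_per_10": self.er_per_10,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "ci_kind": self.ci_kind,
            "dfs": self.dfs, "n_obs": self.n_obs, "dispersion": self.dispersion,
        }


def fit_poisson_glm(
    y: np.ndarray, design: np.ndarray, family: str = "poisson", maxiter: int = 200
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Poisson log-link GLM by IRLS (or OLS for the Gaussian linear analog).

    Returns ``(coefficients, covariance, deviance_residuals)``.  The design
    must include any intercept column explicitly.  Raises on rank-deficient
    designs and on IRLS non-convergence.
    """
    y = np.asarray(y, dtype=float)
    design = np.asarray(design, dtype=float)
    if design.shape[0] != y.size:
        raise DegenerateDataError(
            f"design rows ({design.shape[0]}) != response length ({y.size})"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = np.flatnonzero(diag < 1e-8 * diag.max()).tolist()
        raise RankDeficiencyError(
            f"design rank {rank} < {design.shape[1]} columns; suspect columns {bad}"
        )
    if family == "gaussian":
        model = sm.OLS(y, design)
        res = model.fit()
        return res.params, res.cov_params(), res.resid
    if family != "poisson":
        raise DegenerateDataError(f"unknown family {family!r}")
    if (y < 0).any():
        raise DegenerateDataError("counts must be nonnegative")
    model = sm.GLM(y, design, family=sm.families.Poisson())
    res = model.fit(maxiter=maxiter, tol=1e-10)
    if not res.converged:
        raise FitConvergenceError(
            f"Poisson IRLS did not converge within {maxiter} iterations "
            f"(deviance {res.deviance:.4g})"
        )
    return res.params, res.cov_params(), res.resid_deviance


def _estimate(
    method: str, cause: str, y: np.ndarray, design: np.ndarray, slope_index: int,
    dfs: dict, family: str,
) -> EffectEstimate:
    coef, cov, dev = fit_poisson_glm(y, design, family=family)
    beta = float(coef[slope_index])
    se = float(np.sqrt(cov[slope_index, slope_index]))
    from scipy import stats

    z = beta / se if se > 0 else np.inf
    p = float(2.0 * stats.norm.sf(abs(z)))
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    p_cols = design.shape[1]
    if family == "poisson":
        mu = np.exp(design @ coef)
        pearson = float(np.sum((y - mu) ** 2 / mu))
        dispersion = pearson / max(y.size - p_cols, 1)
    else:
        dispersion = float("nan")
    return EffectEstimate(
        method=method, cause=cause, beta=beta, se_beta=se,
        er_per_10=er_per_10(beta), ci_low=er_per_10(lo), ci_high=er_per_10(hi),
        p_value=p, ci_kind="wald", dfs=dfs, n_obs=int(y.size),
        deviance_residuals=np.asarray(dev), dispersion=dispersion,
    )


def fit_2sps(
    y: np.ndarray,
    first_stage: FirstStageFit,
    time_index: np.ndarray,
    cause: str = "cvd",
    df_time: int = 32,
    family: str = "poisson",
) -> EffectEstimate:
    """Two-stage predictor substitution second stage.

    Counts on ``[1, epsilon1_hat, ns(time, df_time)]``; no day-of-week term
    (short-term fluctuations were already removed from the exposure during
    detrending).
    """
    eps1_hat = first_stage.epsilon1_hat
    if float(np.var(eps1_hat)) == 0:
        raise DegenerateDataError(
            "calibrated instrument epsilon1_hat has zero variance; exposure unidentified"
        )
    X = np.column_stack([
        np.ones(len(eps1_hat)), eps1_hat,
        natural_spline_basis(np.asarray(time_index, float), SplineSpec(df_time)),
    ])
    return _estimate("2SPS", cause, y, X, 1, {"time": df_time}, family)


def fit_cfn(
    y: np.ndarray,
    exposure: np.ndarray,
    first_stage: FirstStageFit,
    time_index: np.ndarray,
    cause: str = "cvd",
    df_time: int = 32,
    df_eps2: int = 17,
    family: str = "poisson",
) -> EffectEstimate:
    """Control-function second stage.

    Counts on ``[1, exposure, ns(epsilon2, df_eps2), ns(time, df_time)]``
    where ``exposure`` is the raw 2-day-mean PM2.5 and ``epsilon2`` the
    first-stage residual acting as a (possibly nonlinear) confounder
    surrogate.  With ``df_eps2=1`` and Gaussian family this reduces to the
    classical linear control function.
    """
    eps2 = first_stage.epsilon2
    if float(np.var(eps2)) == 0:
        # degenerate surrogate: fall back to a zero column so beta is still defined
        ctrl = np.zeros((len(eps2), 0))
        dfs = {"time": df_time, "eps2": 0}
    else:
        ctrl = natural_spline_basis(eps2, SplineSpec(df_eps2))
        dfs = {"time": df_time, "eps2": df_eps2}
    X = np.column_stack([
        np.ones(len(eps2)), np.asarray(exposure, dtype=float), ctrl,
        natural_spline_basis(np.asarray(time_index, float), SplineSpec(df_time)),
    ])
    return _estimate("CFN", cause, y, X, 1, dfs, family)


def fit_gam(
    y: np.ndarray,
    exposure: np.ndarray,
    tem: np.ndarray,
    ozone: np.ndarray,
    dow: np.ndarray,
    time_index: np.ndarray,
    cause: str = "cvd",
    df_time: int = 32,
    df_tem: int = 15,
    df_ozone: int = 23,
    family: str = "poisson",
) -> EffectEstimate:
    """Conventional covariate-adjusted comparator.

    Counts on ``[1, dow dummies, exposure, ns(tem, 15), ns(time, 32),
    ns(ozone, 23)]``.  Fixed-df regression splines (no penalized smoothing),
    matching common practice in daily mortality studies.
    """
    X = np.column_stack([
        np.ones(len(y)),
        dow_dummies(dow),
        np.asarray(exposure, dtype=float),
        natural_spline_basis(np.asarray(tem, float), SplineSpec(df_tem)),
        natural_spline_basis(np.asarray(time_index, float), SplineSpec(df_time)),
        natural_spline_basis(np.asarray(ozone, float), SplineSpec(df_ozone)),
    ])
    dfs = {"time": df_time, "tem": df_tem, "ozone": df_ozone}
    return _estimate("GAM", cause, y, X, 7, dfs, family)
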