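"""IV first stage: calibrating the instrument by support-vector regression.

Boundary-layer height and wind speed drive the dispersion of locally emitted
PM2.5 but have no plausible direct path to daily mortality, which makes them
natural instruments.  The first stage regresses the detrended exposure
``epsilon1`` on lag-0 and lag-1 BLH and WS with an epsilon-insensitive
radial-kernel SVR, combining the four weather features into a single
pollution-calibrated instrument:

* ``epsilon1_hat`` -- the fitted conditional expectation of the detrended
  exposure given the instruments; independent of unobserved confounders
  because the weather is;
* ``epsilon2 = epsilon1 - epsilon1_hat`` -- the first-stage residual, which
  carries whatever confounded variation remains and serves as the
  confounder surrogate in the control-function estimator.

SVR hyperparameters default to ``C = 1``, tube width ``0.1 * sd(epsilon1)``
and scikit-learn's ``gamma='scale'`` kernel width; a contiguous-block
cross-validation tuner over a small grid is available, as is a linear
first stage used in oracle comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .exceptions import ConfigurationError, DegenerateDataError, DimensionError

__all__ = [
    "IVFeatureSpec",
    "FirstStageFit",
    "build_iv_features",
    "fit_first_stage",
    "tune_svr",
    "first_stage_diagnostics",
]

WEAK_INSTRUMENT_THRESHOLD = 0.05


@dataclass(frozen=True)
class IVFeatureSpec:
    """Which instrument columns and lags (or leads) enter the first stage.

    ``lags`` are in days before the outcome day; negative entries are not
    allowed here (leads for negative-control exposures are handled by
    :func:`ivair.inference.build_negative_exposure`).  Columns are z-scored
    with means/SDs of the rows actually used for training.
    """

    lags: tuple[int, ...] = (0, 1)
    variables: tuple[str, ...] = ("blh", "ws")
    standardize: bool = True

    def __post_init__(self) -> None:
        if not self.variables:
            raise ConfigurationError("IVFeatureSpec needs at least one variable")
        if any(l < 0 for l in self.lags):
            raise ConfigurationError(f"lags must be nonnegative, got {self.lags}")
        if list(self.lags) != sorted(self.lags):
            raise ConfigurationError(f"lags must be sorted ascending, got {self.lags}")

    @property
    def column_names(self) -> list[str]:
        return [f"{v}_lag{l}" for v in self.variables for l in self.lags]


def build_iv_features(
    series: pd.DataFrame, spec: IVFeatureSpec = IVFeatureSpec()
) -> tuple[np.ndarray, np.ndarray]:
    """Lagged, standardized instrument feature matrix.

    Returns ``(features, kept_index)`` where ``kept_index`` holds the
    0-based row positions of ``series`` that survive lag availability (the
    first ``max(lags)`` rows are dropped), so outcome rows can be aligned.
    """
    n = len(series)
    max_lag = max(spec.lags)
    if n <= max_lag:
        raise DimensionError(f"series of length {n} too short for max lag {max_lag}")
    kept = np.arange(max_lag, n)
    cols = []
    for v in spec.variables:
        x = series[v].to_numpy(dtype=float)
        for l in spec.lags:
            cols.append(x[kept - l])
    F = np.column_stack(cols)
    const = np.ptp(F, axis=0) == 0
    if const.any():
        names = [spec.column_names[j] for j in np.flatnonzero(const)]
        raise DegenerateDataError(f"constant instrument feature columns: {names}")
    if spec.standardize:
        F = (F - F.mean(axis=0)) / F.std(axis=0)
    return F, kept


@dataclass
class FirstStageFit:
    """First-stage artifacts: calibrated instrument and confounder surrogate.

    The decomposition ``epsilon1_hat + epsilon2 == epsilon1`` holds exactly
    (elementwise) because ``epsilon2`` is defined as the arithmetic
    difference.
    """

    feature_spec: IVFeatureSpec
    hyperparameters: dict
    epsilon1: np.ndarray
    epsilon1_hat: np.ndarray
    epsilon2: np.ndarray
    fraction_remaining_variance_explained: float
    method: str = "svr"
    features: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "lags": list(self.feature_spec.lags),
            "variables": list(self.feature_spec.variables),
            "hyperparameters": self.hyperparameters,
            "fraction_remaining_variance_explained": self.fraction_remaining_variance_explained,
        }


def fit_first_stage(
    epsilon1: np.ndarray,
    features: np.ndarray,
    hyperparameters: dict | None = None,
    feature_spec: IVFeatureSpec = IVFeatureSpec(),
    method: str = "svr",
) -> FirstStageFit:
    """Fit the first-stage regression of ``epsilon1`` on the IV features.

    ``method='svr'`` (default) uses an epsilon-insensitive RBF support-vector
    regression; ``method='linear'`` uses OLS (the linear fallback used in
    oracle comparisons).  Fitted values are in-sample.
    """
    epsilon1 = np.asarray(epsilon1, dtype=float)
    if features.shape[0] != epsilon1.size:
        raise DimensionError(
            f"features rows ({features.shape[0]}) != epsilon1 length ({epsilon1.size})"
        )
    sd1 = float(epsilon1.std())
    hp = dict(hyperparameters or {})
    if method == "svr":
        hp.setdefault("C", 1.0)
        hp.setdefault("epsilon", 0.1 * sd1 if sd1 > 0 else 0.1)
        hp.setdefault("gamma", "scale")
        try:
            svr = SVR(kernel="rbf", C=hp["C"], epsilon=hp["epsilon"], gamma=hp["gamma"])
            svr.fit(features, epsilon1)
            eps1_hat = svr.predict(features)
        except Exception as exc:  # pragma: no cover - sklearn failure path
            raise RuntimeError(f"SVR first stage failed with hyperparameters {hp}: {exc}") from exc
    elif method == "linear":
        X = np.column_stack([np.ones(len(features)), features])
        coef, *_ = np.linalg.lstsq(X, epsilon1, rcond=None)
        eps1_hat = X @ coef
        hp = {"coefficients": coef.tolist()}
    else:
        raise ConfigurationError(f"unknown first-stage method {method!r}")
    eps2 = epsilon1 - eps1_hat
    var1 = float(np.var(epsilon1))
    frac = 0.0 if var1 == 0 else 1.0 - float(np.var(eps2)) / var1
    return FirstStageFit(
        feature_spec=feature_spec, hyperparameters=hp, epsilon1=epsilon1,
        epsilon1_hat=eps1_hat, epsilon2=eps2,
        fraction_remaining_variance_explained=frac, method=method, features=features,
    )


def linear_first_stage_r2(epsilon1: np.ndarray, features: np.ndarray) -> float:
    """In-sample R^2 of the *linear* regression of ``epsilon1`` on the features.

    The canonical weak-instrument diagnostic: unlike the in-sample SVR fit
    (which can explain noise), the linear R^2 is near ``p/n`` when the
    instruments carry no signal.
    """
    epsilon1 = np.asarray(epsilon1, dtype=float)
    if epsilon1.std() == 0:
        return 0.0
    X = np.column_stack([np.ones(len(features)), features])
    coef, *_ = np.linalg.lstsq(X, epsilon1, rcond=None)
    resid = epsilon1 - X @ coef
    return 1.0 - float(np.var(resid)) / float(np.var(epsilon1))


def tune_svr(
    epsilon1: np.ndarray,
    features: np.ndarray,
    c_grid: tuple[float, ...] = (0.3, 1.0, 3.0),
    eps_grid: tuple[float, ...] = (0.05, 0.1, 0.2),
    n_folds: int = 5,
) -> dict:
    """Pick (C, epsilon) by contiguous-block cross-validated MSE.

    ``eps_grid`` entries are multiples of ``sd(epsilon1)``.  Folds are
    contiguous blocks, respecting the serial dependence of daily data.
    Deterministic given the data and grid.
    """
    epsilon1 = np.asarray(epsilon1, dtype=float)
    n = epsilon1.size
    sd1 = float(epsilon1.std()) or 1.0
    bounds = np.linspace(0, n, n_folds + 1, dtype=int)
    best, best_mse = None, np.inf
    for C in c_grid:
        for em in eps_grid:
            sse = 0.0
            for a, b in zip(bounds[:-1], bounds[1:]):
                mask = np.ones(n, dtype=bool)
                mask[a:b] = False
                svr = SVR(kernel="rbf", C=C, epsilon=em * sd1, gamma="scale")
                svr.fit(features[mask], epsilon1[mask])
                sse += float(np.sum((epsilon1[~mask] - svr.predict(features[~mask])) ** 2))
            if sse / n < best_mse:
                best, best_mse = {"C": C, "epsilon": em * sd1, "gamma": "scale"}, sse / n
    return best


def first_stage_diagnostics(
    fit: FirstStageFit, series: pd.DataFrame, kept: np.ndarray
) -> dict:
    """Diagnostics mirroring the validity checks of the IV design.

    Reports the correlation of the calibrated instrument with temperature
    and with the day index (both should be near zero after detrending), the
    correlation between fitted values and residuals, and a weak-instrument
    flag raised when the *linear* first-stage R^2 falls below 5% (the
    in-sample SVR fraction can explain noise, so it is reported but not used
    for the flag).
    """
    tem = series["tem"].to_numpy(dtype=float)[kept]
    day = np.arange(1, len(series) + 1, dtype=float)[kept]

    def _corr(a, b):
        if a.std() == 0 or b.std() == 0:
            return float("nan")
        return float(np.corrcoef(a, b)[0, 1])

    if fit.features is not None:
        r2_linear = linear_first_stage_r2(fit.epsilon1, fit.features)
    else:
        r2_linear = fit.fraction_remaining_variance_explained
    return {
        "corr_eps1hat_tem": _corr(fit.epsilon1_hat, tem),
        "corr_eps1hat_time": _corr(fit.epsilon1_hat, day),
        "corr_eps1hat_eps2": _corr(fit.epsilon1_hat, fit.epsilon2),
        "fraction_remaining_variance_explained": fit.fraction_remaining_variance_explained,
        "linear_first_stage_r2": float(r2_linear),
        "weak_instrument": bool(r2_linear < WEAK_INSTRUMENT_THRESHOLD),
    }
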