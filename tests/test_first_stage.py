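"""First stage: feature building, SVR decomposition, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from ivair.exceptions import ConfigurationError, DegenerateDataError, DimensionError
from ivair.first_stage import (
    IVFeatureSpec,
    build_iv_features,
    first_stage_diagnostics,
    fit_first_stage,
)
from ivair.model import PMMortalityIV
from ivair.synthetic import SyntheticConfig, generate_dataset


def _weather_frame(n=10, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame({"blh": rng.uniform(50, 400, n), "ws": rng.uniform(0.5, 6, n)})


def test_lag0_features_keep_all_rows():
    F, kept = build_iv_features(_weather_frame(10), IVFeatureSpec(lags=(0,)))
    assert F.shape == (10, 2)
    np.testing.assert_array_equal(kept, np.arange(10))


def test_lag1_drops_first_row():
    F, kept = build_iv_features(_weather_frame(10), IVFeatureSpec(lags=(0, 1)))
    assert F.shape == (9, 4)
    np.testing.assert_array_equal(kept, np.arange(1, 10))


def test_standardization_is_exact():
    F, _ = build_iv_features(_weather_frame(200), IVFeatureSpec(lags=(0, 1)))
    np.testing.assert_allclose(F.mean(axis=0), 0, atol=1e-12)
    np.testing.assert_allclose(F.std(axis=0), 1, atol=1e-12)


def test_constant_feature_column_raises():
    df = _weather_frame(20)
    df["blh"] = 100.0
    with pytest.raises(DegenerateDataError):
        build_iv_features(df, IVFeatureSpec(lags=(0,)))


def test_invalid_feature_specs_raise():
    with pytest.raises(ConfigurationError):
        IVFeatureSpec(lags=(-1, 0))
    with pytest.raises(ConfigurationError):
        IVFeatureSpec(variables=())


def test_decomposition_is_exact():
    rng = np.random.default_rng(1)
    F, _ = build_iv_features(_weather_frame(300, seed=2), IVFeatureSpec(lags=(0,)))
    eps1 = 2.0 * F[:, 0] + rng.normal(0, 1, 300)
    fit = fit_first_stage(eps1, F)
    np.testing.assert_allclose(fit.epsilon1_hat + fit.epsilon2, eps1, rtol=0, atol=1e-12)


def test_zero_target_gives_zero_fraction_and_flat_fit():
    F, _ = build_iv_features(_weather_frame(100, seed=3), IVFeatureSpec(lags=(0,)))
    fit = fit_first_stage(np.zeros(100), F)
    assert fit.fraction_remaining_variance_explained == 0.0
    assert np.abs(fit.epsilon1_hat).max() <= fit.hyperparameters["epsilon"] + 1e-8


def test_svr_recovers_linear_signal_and_agrees_with_kernel_ridge():
    rng = np.random.default_rng(4)
    F, _ = build_iv_features(_weather_frame(400, seed=5), IVFeatureSpec(lags=(0,)))
    eps1 = 1.5 * F[:, 0] + rng.normal(0, 0.01, 400)
    fit = fit_first_stage(eps1, F)
    assert fit.fraction_remaining_variance_explained > 0.9
    # independent oracle: closed-form kernel ridge with the same RBF scale
    gamma = 1.0 / (F.shape[1] * F.var())
    sq = ((F[:, None, :] - F[None, :, :]) ** 2).sum(-1)
    K = np.exp(-gamma * sq)
    alpha = np.linalg.solve(K + 1e-3 * np.eye(len(F)), eps1)
    krr_hat = K @ alpha
    krr_frac = 1.0 - np.var(eps1 - krr_hat) / np.var(eps1)
    assert abs(fit.fraction_remaining_variance_explained - krr_frac) < 0.05


def test_wider_tube_never_explains_more():
    rng = np.random.default_rng(6)
    F, _ = build_iv_features(_weather_frame(250, seed=7), IVFeatureSpec(lags=(0,)))
    eps1 = np.sin(F[:, 0]) + 0.5 * F[:, 1] + rng.normal(0, 0.3, 250)
    sd = eps1.std()
    fracs = [
        fit_first_stage(eps1, F, {"epsilon": m * sd}).fraction_remaining_variance_explained
        for m in (0.05, 0.2, 0.5, 1.0)
    ]
    # near-monotone: tiny tubes can jitter by O(1e-3); gross widening must hurt
    assert all(a >= b - 5e-3 for a, b in zip(fracs, fracs[1:])), fracs
    assert fracs[0] > fracs[-1] + 0.05


def test_weak_instrument_flagged_when_iv_strength_zero():
    data, _ = generate_dataset(SyntheticConfig(n_days=400, seed=8, iv_strength=(0.0, 0.0)))
    model = PMMortalityIV(data, causes=("cvd",))
    res = model.fit(methods=("2SPS",))
    assert res.diagnostics["weak_instrument"]


def test_calibrated_instrument_clean_of_temperature_and_confounder():
    # operating premise of the IV design: eps1_hat tracks weather-driven
    # exposure only, eps2 inherits the confounding
    r_tem, r_u, r_u2 = [], [], []
    for seed in range(10):
        data, truth = generate_dataset(SyntheticConfig(seed=seed))
        model = PMMortalityIV(data, causes=("cvd",))
        res = model.fit(methods=("2SPS",))
        r_tem.append(res.diagnostics["corr_eps1hat_tem"])
        U = truth.realized_confounder
        U2 = 0.5 * (U[1:] + U[:-1])
        r_u.append(np.corrcoef(res.first_stage_fit.epsilon1_hat, U2)[0, 1])
        r_u2.append(np.corrcoef(res.first_stage_fit.epsilon2, U2)[0, 1])
    assert abs(np.mean(r_tem)) < 0.1
    assert abs(np.mean(r_u)) < 0.05
    assert np.mean(r_u2) > 0.3


def test_row_mismatch_raises():
    F, _ = build_iv_features(_weather_frame(50), IVFeatureSpec(lags=(0,)))
    with pytest.raises(DimensionError):
        fit_first_stage(np.zeros(49), F)


def test_diagnostics_report_fields(fitted_results):
    model, res, _ = fitted_results
    d = first_stage_diagnostics(res.first_stage_fit, model.series, model.kept)
    assert set(d) >= {"corr_eps1hat_tem", "corr_eps1hat_time", "weak_instrument"}
    assert not d["weak_instrument"]
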