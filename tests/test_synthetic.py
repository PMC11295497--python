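"""Generator contract: determinism, marginal structure, causal knobs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ivair.exceptions import ConfigurationError, DimensionError
from ivair.synthetic import (
    SyntheticConfig,
    generate_confounder,
    generate_dataset,
    generate_deaths,
    generate_pm25,
    generate_weather,
)


def test_identical_seed_gives_bitwise_identical_dataset(tmp_path):
    cfg = SyntheticConfig(n_days=120, seed=9)
    d1, t1 = generate_dataset(cfg, path=tmp_path / "a.csv")
    d2, t2 = generate_dataset(SyntheticConfig(n_days=120, seed=9), path=tmp_path / "b.csv")
    pd.testing.assert_frame_equal(d1, d2)
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
    np.testing.assert_array_equal(t1.realized_confounder, t2.realized_confounder)


def test_different_seeds_give_different_pm():
    d1, _ = generate_dataset(SyntheticConfig(n_days=90, seed=1))
    d2, _ = generate_dataset(SyntheticConfig(n_days=90, seed=2))
    assert not np.array_equal(d1["pm25"], d2["pm25"])


def test_weather_sign_structure_matches_observed_correlations():
    # positive tem-BLH and BLH-WS coupling, as in observed meteorology
    w = generate_weather(SyntheticConfig(seed=4))
    assert stats.spearmanr(w["tem"], w["blh"]).statistic > 0
    assert stats.spearmanr(w["blh"], w["ws"]).statistic > 0
    assert (w["blh"] > 0).all() and (w["ws"] > 0).all()


def test_degenerate_weather_is_constant_temperature():
    cfg = SyntheticConfig(n_days=90, temp_amplitude_K=0.0, temp_ar=0.0, temp_noise_sd=0.0)
    w = generate_weather(cfg)
    np.testing.assert_allclose(w["tem"], cfg.temp_mean_K)


def test_pm_constant_when_all_drivers_off():
    cfg = SyntheticConfig(
        n_days=90, confounder_to_pm=0.0, pm_noise_sd=0.0, iv_strength=(0.0, 0.0),
        pm_seasonal_amplitude=0.0, pm_temp_loading=0.0,
    )
    pm = generate_pm25(generate_weather(cfg), generate_confounder(cfg), cfg)
    np.testing.assert_allclose(pm, cfg.pm_mean)


def test_pm_negative_dependence_on_meteorology():
    cfg = SyntheticConfig(seed=5)
    data, _ = generate_dataset(cfg)
    assert stats.spearmanr(data["tem"], data["pm25"]).statistic < 0
    assert stats.spearmanr(data["blh"], data["pm25"]).statistic < 0
    assert stats.spearmanr(data["ws"], data["pm25"]).statistic < 0


def test_confounder_loading_adds_variance_quadratically():
    # with kappa=5, var(pm) grows by ~25*var(U) (plus the realized cross term)
    base = dict(n_days=1826, seed=6)
    cfg0 = SyntheticConfig(confounder_to_pm=0.0, **base)
    cfg5 = SyntheticConfig(confounder_to_pm=5.0, **base)
    w = generate_weather(cfg0)
    U = generate_confounder(cfg0)
    pm0 = generate_pm25(w, U, cfg0)
    pm5 = generate_pm25(w, U, cfg5)
    observed = np.var(pm5) - np.var(pm0)
    expected = 25.0 * np.var(U) + 10.0 * np.cov(U, pm0, bias=True)[0, 1]
    np.testing.assert_allclose(observed, expected, rtol=1e-10)
    assert 15.0 < observed < 35.0


def test_poisson_mean_identity_with_all_effects_off():
    cfg = SyntheticConfig(
        n_days=1826, seed=7, true_beta=0.0, confounder_to_deaths=0.0,
        mortality_seasonal_amplitude=0.0, dow_effects=(0.0,) * 7,
    )
    data, _ = generate_dataset(cfg)
    for cause, mean_c in cfg.cause_means.items():
        x = data[f"deaths_{cause}"]
        se = np.sqrt(mean_c / cfg.n_days)
        assert abs(x.mean() - mean_c) < 3 * se, cause
        if mean_c > 5:  # variance/mean ratio check needs non-tiny counts
            assert 0.9 < x.var(ddof=1) / x.mean() < 1.1, cause


def test_exposure_shift_scales_death_rate():
    # +10 ug/m3 everywhere with beta=0.001 multiplies the rate by e^0.01
    cfg = SyntheticConfig(
        n_days=1826, seed=8, true_beta=0.001, confounder_to_deaths=0.0,
        mortality_seasonal_amplitude=0.0, dow_effects=(0.0,) * 7,
    )
    w = generate_weather(cfg)
    U = generate_confounder(cfg)
    pm = generate_pm25(w, U, cfg)
    d0 = generate_deaths(pm, U, w, cfg)
    d1 = generate_deaths(pm + 10.0, U, w, cfg)
    ratio = d1["deaths_cvd"].mean() / d0["deaths_cvd"].mean()
    assert abs(ratio - np.exp(0.01)) < 0.01


def test_confounder_independent_of_instruments():
    # the IV independence assumption is built in: U correlates with PM2.5
    # but not with BLH or WS
    r_pm, r_blh, r_ws = [], [], []
    for seed in range(20):
        cfg = SyntheticConfig(seed=seed)
        data, truth = generate_dataset(cfg)
        U = truth.realized_confounder
        r_pm.append(np.corrcoef(U, data["pm25"])[0, 1])
        r_blh.append(np.corrcoef(U, data["blh"])[0, 1])
        r_ws.append(np.corrcoef(U, data["ws"])[0, 1])
    assert np.mean(np.abs(r_pm)) > 0.1
    assert abs(np.mean(r_blh)) < 0.05
    assert abs(np.mean(r_ws)) < 0.05


def test_dataset_table_contract():
    data, truth = generate_dataset(SyntheticConfig(n_days=60, seed=1))
    assert len(data) == 60
    assert not data.isna().any().any()
    assert data["date"].is_monotonic_increasing
    for c in ("cvd", "ihd", "mi", "cva", "htn"):
        col = data[f"deaths_{c}"]
        assert (col >= 0).all() and np.issubdtype(col.dtype, np.integer)
    assert truth.true_er_per_10 == truth.config.true_er_per_10


def test_truth_er_consistent_with_beta():
    cfg = SyntheticConfig(true_beta=np.log(1.01) / 10)
    assert abs(cfg.true_er_per_10 - 1.0) < 1e-12


@pytest.mark.parametrize(
    "field, value",
    [
        ("n_days", 10),
        ("temp_ar", 1.0),
        ("pm_noise_sd", -1.0),
        ("dow_effects", (0.0,) * 6),
    ],
)
def test_invalid_config_raises_naming_field(field, value):
    with pytest.raises(ConfigurationError):
        SyntheticConfig(**{field: value})


def test_length_mismatch_raises():
    cfg = SyntheticConfig(n_days=90)
    w = generate_weather(cfg)
    with pytest.raises(DimensionError):
        generate_pm25(w, np.zeros(50), cfg)
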