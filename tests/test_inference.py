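"""Block bootstrap, negative-control machinery, descriptive operations."""

import numpy as np
import pandas as pd
import pytest

from ivair.exceptions import ConfigurationError, DimensionError
from ivair.inference import (
    BootstrapSpec,
    block_bootstrap,
    block_bootstrap_ci,
    build_negative_exposure,
    default_block_length,
    spearman_matrix,
    summary_stats,
)
from ivair.model import PMMortalityIV
from ivair.synthetic import SyntheticConfig, generate_dataset


def _mean_estimator(frame):
    return float(frame["x"].mean())


# ------------------------------------------------------------- bootstrap core
def test_block_length_one_reduces_to_iid_bootstrap(rng):
    x = rng.normal(0.0, 1.0, 300)
    frame = pd.DataFrame({"x": x})
    spec = BootstrapSpec(n_replicates=1500, block_length=1, seed=5)
    lo, hi, se = block_bootstrap_ci(frame, _mean_estimator, spec)
    # ordinary iid bootstrap of the mean: SE ~ sd/sqrt(n), CI ~ mean +- 1.96 SE
    se_iid = x.std(ddof=1) / np.sqrt(300)
    assert abs(se - se_iid) < 0.15 * se_iid
    assert abs(lo - (x.mean() - 1.96 * se_iid)) < 3 * se_iid
    assert abs(hi - (x.mean() + 1.96 * se_iid)) < 3 * se_iid


def test_ar1_bootstrap_se_matches_long_run_variance(rng):
    # AR(1), phi=0.5: long-run SD of the mean is sigma/((1-phi)*sqrt(n))
    n, phi = 800, 0.5
    e = rng.normal(size=n)
    x = np.empty(n)
    x[0] = e[0] / np.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    frame = pd.DataFrame({"x": x})
    spec = BootstrapSpec(n_replicates=2000, block_length=25, seed=7)
    _, _, se = block_bootstrap_ci(frame, _mean_estimator, spec)
    se_analytic = 1.0 / ((1 - phi) * np.sqrt(n))
    assert abs(se - se_analytic) < 0.15 * se_analytic


def test_bootstrap_is_deterministic_given_seed(rng):
    frame = pd.DataFrame({"x": rng.normal(size=200)})
    spec = BootstrapSpec(n_replicates=300, block_length=10, seed=3)
    a = block_bootstrap_ci(frame, _mean_estimator, spec)
    b = block_bootstrap_ci(frame, _mean_estimator, spec)
    assert a == b


def test_block_bootstrap_wider_than_iid_on_autocorrelated_pipeline_data():
    # the exposure series is seasonally and serially correlated; honouring
    # blocks must widen the interval relative to resampling single days
    wider = 0
    n_seeds = 12
    for seed in range(n_seeds):
        data, _ = generate_dataset(SyntheticConfig(n_days=800, seed=seed))
        frame = PMMortalityIV(data, causes=("cvd",)).frame
        lo_b, hi_b, _ = block_bootstrap_ci(
            frame, _mean_estimator, BootstrapSpec(n_replicates=400, block_length=20, seed=seed)
        )
        lo_i, hi_i, _ = block_bootstrap_ci(
            frame, _mean_estimator, BootstrapSpec(n_replicates=400, block_length=1, seed=seed)
        )
        wider += (hi_b - lo_b) >= (hi_i - lo_i)
    assert wider / n_seeds >= 0.8


def test_failure_rate_above_ten_percent_raises(rng):
    frame = pd.DataFrame({"x": rng.normal(size=100)})

    calls = {"n": 0}

    def flaky(f):
        calls["n"] += 1
        if calls["n"] % 3 == 0:
            raise ValueError("boom")
        return float(f["x"].mean())

    from ivair.exceptions import InferenceError

    with pytest.raises(InferenceError):
        block_bootstrap(frame, flaky, BootstrapSpec(n_replicates=300, block_length=5, seed=1))


def test_block_length_rule_on_white_noise_and_ar(rng):
    assert default_block_length(rng.normal(size=2000)) <= 3
    phi, n = 0.9, 2000
    x = np.empty(n)
    e = rng.normal(size=n)
    x[0] = e[0]
    for t in range(1, n):
        x[t] = phi * x[t - 1] + e[t]
    assert default_block_length(x) > 10


def test_invalid_bootstrap_specs_raise():
    with pytest.raises(ConfigurationError):
        BootstrapSpec(n_replicates=0)
    with pytest.raises(ConfigurationError):
        BootstrapSpec(ci_level=1.2)
    with pytest.raises(ConfigurationError):
        BootstrapSpec(scheme="stationary")


# ------------------------------------------------------------ negative control
def test_negative_exposure_alignment_lengths():
    data, _ = generate_dataset(SyntheticConfig(n_days=100, seed=2))
    eps1 = np.arange(100, dtype=float)  # placeholder target, alignment only
    prime, kept_nc = build_negative_exposure(data, eps1, np.arange(100), leads=(1, 2))
    assert len(prime) == 98
    np.testing.assert_array_equal(kept_nc, np.arange(98))


def test_empty_leads_raise():
    data, _ = generate_dataset(SyntheticConfig(n_days=100, seed=2))
    with pytest.raises(ConfigurationError):
        build_negative_exposure(data, np.zeros(100), np.arange(100), leads=())


def test_negative_control_passes_on_default_synthetic(fitted_results):
    _, res, _ = fitted_results
    nc = res.negative_control(causes=("cvd",))["cvd"]
    assert 0.0 <= nc.p_value <= 1.0
    assert nc.leads == (1, 2)
    # exposure coefficient should barely move when the negative term is added
    assert abs(nc.coef_exposure_with_negative - nc.coef_exposure_without_negative) < 5e-4


# --------------------------------------------------------------- descriptives
def test_spearman_hand_computed_example():
    df = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 1, 4, 3, 5]})
    # d^2 = (1,1,1,1,0): rho = 1 - 6*4/(5*24) = 0.8
    m = spearman_matrix(df, ["x", "y"])
    assert abs(m.loc["x", "y"] - 0.8) < 1e-12
    assert m.loc["x", "x"] == 1.0


def test_spearman_constant_column_flagged_nan():
    df = pd.DataFrame({"x": [1, 2, 3, 4], "c": [7, 7, 7, 7]})
    m = spearman_matrix(df, ["x", "c"])
    assert np.isnan(m.loc["x", "c"])


def test_spearman_needs_three_rows():
    with pytest.raises(DimensionError):
        spearman_matrix(pd.DataFrame({"x": [1, 2], "y": [3, 4]}), ["x", "y"])


def test_summary_stats_quantile_convention():
    df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0, 100.0], "c": [5.0] * 5})
    s = summary_stats(df, ["v", "c"])
    assert s.loc["v", "median"] == 3.0
    assert s.loc["v", "p75"] == 4.0  # linear-interpolation quantile rule
    assert s.loc["c", "sd"] == 0.0
    assert s.loc["c", "min"] == s.loc["c", "max"]
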