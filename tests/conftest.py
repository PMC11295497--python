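import numpy as np
import pytest

from ivair.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (5 years, all causes) shared across tests."""
    return generate_dataset(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def small_dataset():
    """A short series (200 days) for fast structural checks."""
    return generate_dataset(SyntheticConfig(n_days=200, seed=3))


@pytest.fixture(scope="session")
def fitted_results(default_dataset):
    """Fitted model (CVD only) on the default dataset, shared where possible."""
    from ivair.model import PMMortalityIV

    data, truth = default_dataset
    model = PMMortalityIV(data, causes=("cvd",))
    return model, model.fit(), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
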