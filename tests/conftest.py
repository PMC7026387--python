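import numpy as np
import pytest

from deepsol.synthetic import SyntheticGroundTruth, generate_dataset, generate_fixture_tables


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The fixed 20-row compound table + matching descriptor CSV."""
    d = tmp_path_factory.mktemp("fixture")
    generate_fixture_tables(d)
    return d


@pytest.fixture(scope="session")
def small_synthetic():
    """300 synthetic compounds from a planted linear mechanism (seeded)."""
    truth = SyntheticGroundTruth.random(k_active=20, seed=7, noise_sd=0.2, weight_scale=0.5)
    fm, ds = generate_dataset(300, truth)
    return truth, fm, ds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
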