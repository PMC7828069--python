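import numpy as np
import pytest

from marbliq.synthetic import generate_cutlet_image, generate_feature_table


@pytest.fixture(scope="session")
def clean_cutlet():
    """Noise-free synthetic cutlet with 30 planted flecks, all >= 10 px."""
    return generate_cutlet_image(n_flecks=30, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def cutlet_with_artifacts():
    """Noise-free cutlet with 25 flecks plus 8 sub-threshold specks."""
    return generate_cutlet_image(n_flecks=25, noise_sd=0.0, seed=3, inject_artifacts=8)


@pytest.fixture(scope="session")
def feature_table():
    return generate_feature_table(39, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
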