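import numpy as np
import pytest

from histofuse import make_feature_table, make_synthetic_histology


@pytest.fixture(scope="session")
def planted_table():
    """Reference planted table: 200 samples, 60 features, 8 informative
    columns at effect size 2, 4 classes."""
    return make_feature_table(n=200, d=60, k_informative=8, effect_size=2.0,
                              K=4, seed=1)


@pytest.fixture(scope="session")
def small_images():
    """Tiny 2-class image set for fast structural tests."""
    return make_synthetic_histology(n_per_class=4, K=2, side=48, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
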