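import numpy as np
import pytest

from mpmtex import FeatureSpec, SyntheticConfig, features_table, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort for fast structural tests: 2 matched patients,
    4 tiles/sample, quarter-size FoVs."""
    return SyntheticConfig(
        n_matched_patients=2, tiles_per_sample=4, fov_shape=(48, 96), seed=11
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_table(small_cohort):
    """Reduced-SHG feature table of the tiny cohort (16 rows, 42 features)."""
    return features_table(small_cohort, FeatureSpec.reduced_shg())
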