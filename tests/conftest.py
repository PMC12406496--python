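import numpy as np
import pandas as pd
import pytest

from tbiharm import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Tiny cohort for fast structural tests."""
    return CohortConfig(
        shape=(16, 12, 16), sham_counts=(4, 4, 4, 4),
        tbi_counts=(5, 5, 5, 5), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Mid-sized cohort without the outlier site, for harmonization tests."""
    cfg = CohortConfig(
        n_sites=3, shape=(20, 16, 24),
        sham_counts=(8, 8, 8), tbi_counts=(10, 10, 10),
        site_offsets=(0.0, 0.04, -0.03), site_scales=(1.0, 1.08, 0.94),
        hemisphere=("left", "left", "left"),
        outlier_site=None, seed=5)
    return generate_cohort(cfg)


@pytest.fixture
def count_annotations():
    rng = np.random.default_rng(3)
    n = 100
    return pd.DataFrame({
        "site": np.repeat([1, 2], n // 2),
        "group": np.tile(["sham", "tbi"], n // 2),
        "sex": rng.choice(["M", "F"], n),
        "atrophy": rng.normal(20, 5, n),
        "day": np.tile([3, 30], n // 2),
    })
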