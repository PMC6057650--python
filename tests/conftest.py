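import numpy as np
import pytest

from trioaudit import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def base_cohort():
    """A small untreated cohort with planted DNMs, mosaics and artifacts."""
    config = SimConfig(seed=11, chrom_len=200_000, embryo_count_per_group=3)
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def clean_cohort():
    """Noise-free cohort (no stray alt reads) for recovery assertions."""
    config = SimConfig(seed=13, chrom_len=200_000, embryo_count_per_group=3,
                       error_rate=0.0)
    return simulate_cohort(config)
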