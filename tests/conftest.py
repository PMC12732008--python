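import numpy as np
import pytest

from usvtwin.source import SourceConfig, sample_cohort, reference_count_cohort


@pytest.fixture(scope="session")
def source_cohort():
    """One default synthetic source cohort (n=90) under a fixed seed."""
    return sample_cohort(SourceConfig(), seed=1)


@pytest.fixture(scope="session")
def reference_cohort():
    """Deterministic cohort realizing the published per-arm counts."""
    return reference_count_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
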