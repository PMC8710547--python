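import numpy as np
import pytest

import funconn as fc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced cohort reused by tests that only need the data structure."""
    cfg = fc.CohortConfig(
        n_per_group=(6, 5, 5), n_regions=30, n_volumes=120, module_count=8, seed=99
    )
    return fc.generate_cohort(cfg)
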