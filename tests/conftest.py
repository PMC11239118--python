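import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import traitgaps as tg

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_clade():
    """A 60-tip clade reused by read-only tests."""
    return tg.build_clade(n_tips=60, n_genera=8, n_families=3, n_cells=20, seed=11)


@pytest.fixture(scope="session")
def small_filterset(small_clade):
    cov = tg.tree_to_covariance(small_clade.tree)
    return tg.derive_filters(cov, tree_id="t0")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
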