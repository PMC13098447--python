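import numpy as np
import pytest

from fibrouq.synthetic_histology import DEFAULT_PALETTES, FiberSpec, make_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """12 synthetic 64 px tiles over the two default palettes (fast shared fixture)."""
    tiles, split = make_cohort(
        DEFAULT_PALETTES, FiberSpec(), n_tiles=12, artifact_rate=0.0, seed=5, size=64
    )
    return tiles, split


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
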