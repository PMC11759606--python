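import numpy as np
import pytest

from pathomil.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Planted-signal cohort small enough for fast unit tests."""
    cfg = CohortConfig(n_patients=12, tiles_per_slide=16, tile_size=32, seed=7)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
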