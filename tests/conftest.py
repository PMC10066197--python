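import numpy as np
import pytest

from divstab import SimConfig, simulate_survey


@pytest.fixture(scope="session")
def tiny_survey():
    """Small 3-site survey shared by IO/pipeline tests."""
    cfg = SimConfig(n_sites=3, n_blocks_per_site=4, pool_size_range=(4, 12), seed=11)
    data, truth = simulate_survey(cfg)
    return data, truth, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
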