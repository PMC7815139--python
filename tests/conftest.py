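import numpy as np
import pytest

from stmort import synthetic, variogram as vg


@pytest.fixture(scope="session")
def borough_field():
    """One borough-scale synthetic field shared by read-only tests."""
    return synthetic.borough_scene(seed=7)


@pytest.fixture(scope="session")
def small_field():
    """Tiny field (5 sites x 3 times) for brute-force comparisons."""
    rng = np.random.default_rng(11)
    lon = -99.15 + rng.uniform(0, 0.25, 5)
    lat = 19.4 + rng.uniform(0, 0.25, 5)
    times = np.array([2000.0, 2001.0, 2002.0])
    ss = np.repeat(np.arange(5), 3)
    return vg.STDataset(
        np.array([f"s{i}" for i in ss], dtype=object),
        lon[ss], lat[ss], np.tile(times, 5), rng.normal(5.0, 1.0, 15))


@pytest.fixture(scope="session")
def sum_metric_model():
    return synthetic.default_st_model()
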