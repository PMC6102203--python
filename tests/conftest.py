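import numpy as np
import pytest

import microtem as mt


def small_config(**kw):
    """A fast simulation configuration: short field, few slices/frames."""
    defaults = dict(fov_length_um=150.0, n_cells=4, n_frames=3,
                    z_slices=24, seed=7)
    defaults.update(kw)
    return mt.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_sample(small_cfg):
    """One small rendered sample with its ground truth."""
    series, truth = mt.simulate_timelapse(small_cfg)
    return series, truth


@pytest.fixture(scope="session")
def noisefree_frame():
    """A noise-free single frame with two well-separated cells."""
    cfg = small_config(n_cells=2, n_frames=1, seed=11)
    src = mt.SyntheticSource(cfg, noise=False)
    bf, gfp = src.get_frame(0)
    return cfg, src.truth, bf, gfp


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
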