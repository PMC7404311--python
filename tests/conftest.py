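import numpy as np
import pytest

from micromorph.io_core import AssayConfig


@pytest.fixture(scope="session")
def disc700_cfg() -> AssayConfig:
    return AssayConfig(pattern_shape="disc", pattern_area=700.0)


@pytest.fixture(scope="session")
def crossbow_cfg() -> AssayConfig:
    return AssayConfig(pattern_shape="crossbow", pattern_area=1100.0)


@pytest.fixture(scope="session")
def single_cell_scene():
    """One rendered single-cell field shared by read-only tests."""
    from micromorph.synthetic_data import make_single_cell

    return make_single_cell(seed=1, snr=10, n_sites=30, site_area_range=(0.2, 2.0))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
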