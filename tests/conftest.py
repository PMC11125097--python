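import numpy as np
import pytest

from fluoroloc import Config, RigGeometry, build_layout


@pytest.fixture(scope="session")
def config():
    return Config.default()


@pytest.fixture(scope="session")
def layout(config):
    return config.layout()


@pytest.fixture(scope="session")
def rig(config):
    return config.rig


@pytest.fixture(scope="session")
def demo_rig():
    """Rig with the small worked-example parameters c=100, d=10."""
    return RigGeometry(camera_height_cm=100.0, mirror_offset_cm=10.0, mirror_angle_deg=45.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_layout():
    return build_layout(width=256, height=256, mc_fraction=0.3, margin_px=4)
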