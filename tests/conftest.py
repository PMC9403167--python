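import numpy as np
import pytest

from dotdiff import OpticalProperties, default_probe
from dotdiff.synthdata import ChestWall, Scene, TargetSpec


@pytest.fixture(scope="session")
def geometry():
    return default_probe()


@pytest.fixture
def props():
    return OpticalProperties(mua=0.02, musp=7.0)


def make_plain_scene(
    depth=2.0,
    radius=1.0,
    target_mua=0.2,
    bg_mua=0.02,
    bg_musp=7.0,
    x=0.0,
    y=0.0,
    wall=False,
    wall_depth=3.0,
):
    """A hand-specified scene without heterogeneity, for deterministic checks."""
    return Scene(
        background=OpticalProperties(mua=bg_mua, musp=bg_musp),
        target=TargetSpec(
            shape="sphere", center=(x, y, depth), radius=radius,
            mua=target_mua, musp=7.0,
        ),
        chest_wall=ChestWall(present=wall, depth=wall_depth),
        hetero_amplitude=0.0,
        hetero_seed=0,
    )


@pytest.fixture
def plain_scene():
    return make_plain_scene()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
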