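import numpy as np
import pytest

from earseg.image_stack import CHANNEL_NAMES, AcquisitionMeta, MultiChannelImage
from earseg.synthetic import SceneParams, generate_canopy


@pytest.fixture
def meta():
    return AcquisitionMeta(days_after_sowing=240, irradiance_E=80.0, zenith_z=30.0)


@pytest.fixture
def small_stack(meta):
    """Deterministic 40x50 stack with all nine channels."""
    rng = np.random.default_rng(7)
    channels = {name: rng.integers(0, 256, (40, 50), dtype=np.uint8)
                for name in CHANNEL_NAMES}
    return MultiChannelImage(channels=channels, meta=meta, image_id="small")


@pytest.fixture(scope="session")
def diffuse_scene():
    """256x256 diffuse canopy with known truth (mature-stage colors)."""
    return generate_canopy(
        SceneParams(height=256, width=256, ear_fraction=0.12, seed=11),
        image_id="diffuse",
    )


@pytest.fixture(scope="session")
def direct_scene():
    """512x512 canopy under direct sun with cast shadows."""
    return generate_canopy(
        SceneParams(height=512, width=512, ear_fraction=0.12,
                    illumination="direct", seed=3),
        image_id="direct",
    )
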