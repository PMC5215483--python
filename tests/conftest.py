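import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from synquant import SectionStack

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_stack(voxels, pixel_size_um=0.1, channels=None, **kw):
    voxels = np.asarray(voxels, dtype=np.float32)
    return SectionStack(
        voxels=voxels,
        pixel_size_um=pixel_size_um,
        channel_names=tuple(channels) if channels else (),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
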