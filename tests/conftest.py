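import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from biomux import ChannelConfig, ChannelMap, default_plan


@pytest.fixture
def cmap32():
    """Full 4-device, 32-channel EEG map."""
    return ChannelMap.uniform(4, 8)


@pytest.fixture
def mixed_cmap():
    """Small mixed map: 4 EEG + 1 optical detector."""
    return ChannelMap.from_channels(
        [ChannelConfig(f"E{i + 1}", role="eeg") for i in range(4)]
        + [ChannelConfig("D1", role="optical", gain=1)]
    )


@pytest.fixture
def plan4():
    """2 sources x 2 wavelengths, no blanking: N_state = 4 at 250 SPS."""
    return default_plan(2, 250, 50.0, blanking_frames=0)
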