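import numpy as np
import pytest

from twitchscope import ImageConfig, TwitchParameters


@pytest.fixture
def reference_params() -> TwitchParameters:
    """A twitch with convenient closed-form constants (k ~ 0.182, m ~ 3.64)."""
    return TwitchParameters(T_c=20.0, T_hr=35.0, F_max=1.0, delay=0.0)


@pytest.fixture
def acquisition_grid() -> np.ndarray:
    """Time grid of an averaged twitch window at the 1.09 kHz line rate."""
    return np.arange(-50.0, 450.0, 1000.0 / 1090.0)


@pytest.fixture
def fast_image_config() -> ImageConfig:
    """Few sweeps and a small field: keeps render-based tests quick."""
    return ImageConfig(n_sweeps=4, field_px=64, snr=50.0)
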