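import numpy as np
import pytest

from stripsense.config import RunConfig
from stripsense.scene import ColorModel, SceneSpec, render_scene


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_scene():
    """Neutral cast, zero tilt, zero pixel noise, zero color noise: exact truth."""
    spec = SceneSpec(concentration=1.0, seed=123, noise_sd=0.0)
    model = ColorModel(color_noise_sd=0.0)
    return render_scene(spec, model)


@pytest.fixture(scope="session")
def noisy_scene():
    """Realistic capture: warm cast, 5 degree tilt, pixel noise."""
    spec = SceneSpec(concentration=1.0, seed=123, noise_sd=2.0, tilt_deg=5.0, lighting_cast="warm")
    return render_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
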