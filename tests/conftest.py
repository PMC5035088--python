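import numpy as np
import pytest

from mmtrace.io_stack import Calibration
from mmtrace.synthetic import GrowthParams, SceneConfig, generate_stack


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def calibration():
    return Calibration(pixel_size_um=0.065, frame_interval_min=5.0)


@pytest.fixture(scope="session")
def small_scene():
    """A 6-channel, 60-frame scene with rotation and drift, plus its truth."""
    config = SceneConfig(
        n_channels=6,
        width_px=260,
        n_frames=60,
        seed=7,
        rotation_deg=0.8,
        drift_step_px=0.4,
        phase_px=28.0,
    )
    series, truth = generate_stack(config, GrowthParams(doubling_time_h=1.3))
    return config, series, truth


@pytest.fixture(scope="session")
def small_scene_analysis(small_scene):
    from mmtrace.pipeline import analyze_series

    _config, series, _truth = small_scene
    return analyze_series(series)
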