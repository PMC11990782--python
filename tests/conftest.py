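import numpy as np
import pytest

from uavtrack.synthetic import ScenarioConfig, simulate_scenario


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def quiet_scenario():
    """Small noiseless scene: perfect detections, static camera."""
    cfg = ScenarioConfig(
        n_targets=5,
        n_frames=20,
        cam_translation_std=0.0,
        cam_rotation_std_deg=0.0,
        cam_zoom_std=0.0,
        occlusion_rate=0.0,
        miss_rate=0.0,
        bbox_jitter_std=0.0,
        false_positive_rate=0.0,
        conf_noise_std=0.0,
        descriptor_noise_std=0.0,
        seed=7,
    )
    return simulate_scenario(cfg)


@pytest.fixture(scope="session")
def jittery_scenario():
    """Default study conditions: camera jitter, occlusion, detection noise."""
    return simulate_scenario(ScenarioConfig(seed=11))
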