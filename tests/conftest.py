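import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", max_examples=50, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from dorsitrack.synth_cohort import (MotionModel, SceneConfig, default_layers,
                                     render_sequence)


@pytest.fixture(scope="session")
def small_scene():
    """Reduced-resolution scene for fast rendering in unit tests."""
    return SceneConfig(image_size=(120, 110), pixel_spacing_mm=(0.33, 0.35),
                       frame_rate_hz=25.0, seed=7)


@pytest.fixture(scope="session")
def short_motion():
    return MotionModel(n_cycles=2, rest_frames=5)


@pytest.fixture(scope="session")
def phantom(small_scene, short_motion):
    """One rendered two-cycle phantom with mixed-sign layer strains."""
    amps = {"TR": 5.0, "SP": -10.0, "Scap": 8.0, "Scerv": -3.0, "MF": 10.0}
    layers = default_layers(amplitudes=amps)
    seq, truth = render_sequence(small_scene, layers, short_motion)
    return seq, truth, amps


@pytest.fixture(scope="session")
def roi_depths():
    """Layer mid-depths (mm) of the default phantom geometry."""
    return {"TR": 5.0, "SP": 12.0, "Scap": 19.0, "Scerv": 26.0, "MF": 33.0}
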