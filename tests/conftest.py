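import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phonovision import Calibration, GlottalKinematics, generate_glottal_video
from phonovision.segmentation import area_waveform

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def calib():
    return Calibration()  # 20,000 fps, 0.01 mm/px


@pytest.fixture(scope="session")
def sym_video(calib):
    """Noise-free symmetric oscillation, 250 Hz, 2 cycles (160 frames)."""
    kin = GlottalKinematics(f0=250.0, duration=0.008)
    return generate_glottal_video(kin, calib, noise_sigma=0.0, seed=11)


@pytest.fixture(scope="session")
def sym_segmented(sym_video):
    stack, _ = sym_video
    return area_waveform(stack)


@pytest.fixture(scope="session")
def asym_video(calib):
    """2:1 left/right amplitude asymmetry with full collision closure."""
    kin = GlottalKinematics(
        f0=250.0, rest_gap=0.0, amp_left=0.4, amp_right=0.2, duration=0.008
    )
    return generate_glottal_video(kin, calib, noise_sigma=0.0, seed=12)


@pytest.fixture(scope="session")
def asym_segmented(asym_video):
    stack, _ = asym_video
    return area_waveform(stack)


@pytest.fixture(scope="session")
def lag_video(calib):
    """Symmetric oscillation with a pi/4 anterior-posterior phase lag."""
    kin = GlottalKinematics(f0=250.0, ap_phase_lag=np.pi / 4, duration=0.008)
    return generate_glottal_video(kin, calib, noise_sigma=0.0, seed=13)


@pytest.fixture(scope="session")
def static_stack(calib):
    """A non-oscillating (rest slit only) stack."""
    kin = GlottalKinematics(amp_left=0.0, amp_right=0.0, duration=0.002)
    stack, _ = generate_glottal_video(kin, calib, noise_sigma=0.0, seed=14)
    return stack
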