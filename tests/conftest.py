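import numpy as np
import pytest

from retinaln.stimulus import make_gaussian_noise
from retinaln.synth import make_ground_truth_filter


@pytest.fixture(scope="session")
def noise_stim():
    """Standard photopic noise ensemble: 50% contrast SD, 0-60 Hz, 60 s."""
    return make_gaussian_noise(
        mean_level=1000.0, contrast_sd=0.5, bandwidth_hz=60.0,
        duration_s=60.0, dt_s=1e-3, seed=4242,
    )


@pytest.fixture(scope="session")
def biphasic_filter():
    """Reference biphasic kernel with fine-grid ground-truth metadata."""
    return make_ground_truth_filter(
        peak_amp=1.0, trough_amp=0.6, tau_rise_s=0.05, tau_damp_s=0.08,
        dt_s=1e-3, T_filt_s=0.5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(987654321)
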