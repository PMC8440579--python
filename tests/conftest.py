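import numpy as np
import pytest

from smlife import simkit


@pytest.fixture(scope="session")
def noise_free():
    """Photophysics with every stochastic term switched off."""
    return simkit.PhotophysicsParams(
        spot_amplitude_counts=800.0,
        background_counts=0.0,
        read_noise_sd_counts=0.0,
        shot_noise=False,
        bleach_rate_per_exposure=0.0,
        amplitude_cv=0.0,
    )


@pytest.fixture(scope="session")
def acq_halfsec():
    return simkit.AcquisitionParams(frame_interval_s=0.5, exposure_s=0.5, n_frames=60)


@pytest.fixture(scope="session")
def small_movie():
    """A small moderate-noise movie with manifest, shared across tests."""
    acq = simkit.AcquisitionParams(n_frames=240)
    movie, mask, manifest = simkit.render_movie(
        8,
        3,
        simkit.DwellModel(mode="exponential", tau_s=5.0),
        acq,
        simkit.PhotophysicsParams(),
        image_shape=(250, 250),
        seed=7,
    )
    return movie, mask, manifest, acq


def make_two_level_trace(rng, n_frames=240, level=800.0, sd=20.0, events=((60, 80),)):
    path = np.zeros(n_frames)
    for a, b in events:
        path[a:b] = 1.0
    return level * path + rng.normal(0.0, sd, n_frames), path
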