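import math

import numpy as np
import pytest

from mirrorgame import HandParams, ModelConfig


@pytest.fixture
def hands():
    """Virtual-player hand parameters at training-trial magnitudes."""
    return (
        HandParams([0.343, 1.3, 0.25], 0.163, 2.695, "right"),
        HandParams([0.343, 1.3, -0.25], 0.161, 2.698, "left"),
    )


@pytest.fixture
def quiet_config():
    """No coupling, no noise: the analytically tractable regime."""
    return ModelConfig(k_inter=0.0, k_intra=0.0, noise_amplitude=0.0)


def whole_period_circle(
    center=(0.343, 1.3, 0.25),
    radius=0.163,
    cycles=26,
    side="right",
    duration=60.0,
    sample_rate=50.0,
    rng=None,
    noise_sd=0.0,
):
    """Circle spanning an exact number of cycles (no duplicated endpoint),
    so sample means recover centre/radius/frequency to float precision."""
    from mirrorgame import HandTrajectory

    n = int(round(duration * sample_rate))
    times = np.arange(n) / sample_rate
    omega = 2.0 * math.pi * cycles / duration
    theta = omega * times
    sign = 1.0 if side == "right" else -1.0
    pos = np.tile(np.asarray(center, dtype=float), (n, 1))
    pos[:, 1] += radius * np.sin(theta)
    pos[:, 2] += sign * radius * np.cos(theta)
    if noise_sd > 0:
        pos = pos + rng.normal(0.0, noise_sd, pos.shape)
    return HandTrajectory(side, times, pos), omega
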