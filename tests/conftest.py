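import numpy as np
import pytest

from smstoich import simulate


@pytest.fixture
def quiet_acq():
    """Noise-free acquisition with zero background (trajectory-level tests)."""
    return simulate.AcquisitionParams(
        n_frames=120, shot_noise=False, read_noise_sd=0.0, background_mean=0.0
    )


@pytest.fixture
def snr8_acq():
    """Read-noise-only acquisition giving SNR 8 with the unit fluorophore."""
    return simulate.AcquisitionParams(
        n_frames=300, shot_noise=False, read_noise_sd=25.0, background_mean=0.0
    )


@pytest.fixture
def unit_fluor():
    """200-count fluorophore with 20% brightness dispersion."""
    return simulate.FluorophoreModel(i_step_mean=200.0, i_step_cv=0.2, bleach_rate=0.01)


@pytest.fixture
def fixed_fluor():
    """Dispersion-free fluorophore for exact staircase construction."""
    return simulate.FluorophoreModel(i_step_mean=200.0, i_step_cv=0.0, bleach_rate=0.01)


def make_staircase(n_steps, step=100.0, spacing=10, first=10, n_frames=None, noise_sd=0.0, seed=0):
    """Deterministic staircase trace ending at baseline 0."""
    if n_frames is None:
        n_frames = first + spacing * n_steps + 20
    x = np.zeros(n_frames)
    for i in range(n_steps):
        x[: first + i * spacing] += step
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, n_frames)
    return x
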