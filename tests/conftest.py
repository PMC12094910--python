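import numpy as np
import pytest

from oispipe.config import SpectroConfig
from oispipe.synthetic import render_reflectance, simulate_hemodynamics


@pytest.fixture(scope="session")
def cfg() -> SpectroConfig:
    return SpectroConfig()


@pytest.fixture(scope="session")
def small_scene():
    """Compact noiseless planted scene shared by spectroscopy/ROI tests."""
    sim = simulate_hemodynamics(
        shape=(32, 32),
        duration_s=30.0,
        frame_rate_hz=16.0,
        trigger_times_s=(10.0,),
        stim_duration_s=2.0,
        peak_dhbt_uM=2.0,
    )
    return sim


@pytest.fixture(scope="session")
def small_stack(cfg, small_scene):
    return render_reflectance(
        small_scene["dhbo"],
        small_scene["dhbr"],
        cfg,
        noise_sigma=0.0,
        frame_rate_hz=16.0,
        trigger_times_s=small_scene["trigger_times_s"],
        stim_duration_s=2.0,
    )


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return 2.0 * (a & b).sum() / denom if denom else 1.0
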