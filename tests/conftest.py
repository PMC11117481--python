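import numpy as np
import pytest

import pdwear
from pdwear.io import RunConfig


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def detectors(config):
    """Factory-trained detectors, shared across the whole suite."""
    return pdwear.train_detectors(config)


@pytest.fixture(scope="session")
def walk_recording():
    """Noise-free scripted recording: 60 s rest, 60 s walk, 60 s rest."""
    profile = pdwear.SubjectProfile("walker", gait_cadence=120.0, leg_length=0.9)
    return profile, pdwear.simulate_subject(
        profile, 180.0, seed=2, noise=0.0,
        schedule=[("rest", 60), ("walking", 60), ("rest", 60)])


@pytest.fixture(scope="session")
def mixed_recording():
    """One busy labeled hour with dyskinesia and freezing episodes."""
    profile = pdwear.SubjectProfile(
        "mixed", has_dys=True, has_fog=True, dys_rate=6.0, fog_rate=10.0,
        gait_cadence=115.0)
    return profile, pdwear.simulate_subject(profile, 3600.0, seed=12)


def make_frame(x, y=None, z=None, fs=50.0):
    """Build a single Frame from per-axis arrays (defaults: zeros)."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x) if y is None else np.asarray(y, dtype=float)
    z = np.zeros_like(x) if z is None else np.asarray(z, dtype=float)
    from pdwear.features import Frame
    return Frame(start_s=0.0, duration_s=len(x) / fs,
                 samples=np.column_stack([x, y, z]), sampling_rate=fs)
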