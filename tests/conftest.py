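import numpy as np
import pytest

from swapet.io import Hypnogram, HypnogramEpoch, Recording
from swapet.synth import StageComponent, SyntheticPSGSpec, synthesize_recording

FS = 500.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_recording():
    """60-s two-channel recording: 0.7 Hz + 10 Hz mixture on Fz, flat Cz."""
    t = np.arange(int(60 * FS)) / FS
    x = 30 * np.sin(2 * np.pi * 0.7 * t) + 30 * np.sin(2 * np.pi * 10 * t)
    rec = Recording({"Fz": x, "Cz": np.zeros_like(x), "A1": np.zeros_like(x), "A2": np.zeros_like(x)}, fs=FS)
    hyp = Hypnogram([HypnogramEpoch(i, "N2") for i in range(2)])
    return rec, hyp


@pytest.fixture
def event_night():
    """30-min N3-only night of isolated SO (35 µV, 0.7 Hz) and delta
    (20 µV, 2 Hz) slow-wave event trains with known analytic downslopes."""
    spec = SyntheticPSGSpec(
        stage_sequence=[("N3", 60)],
        components={
            "N3": [
                StageComponent("events", 35.0, 0.7, density=6.0),
                StageComponent("events", 20.0, 2.0, density=12.0),
            ]
        },
        seed=7,
    )
    return synthesize_recording(spec)
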