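import numpy as np
import pytest

from wavemotif.recording import RawRecording
from wavemotif.synthetic import ShapeParams, SimulationSpec, SourceSpec, make_recording

FS = 250.0


@pytest.fixture(scope="session")
def single_source_recording():
    """One 10 Hz alpha source with mild asymmetry mixed into 8 channels."""
    spec = SimulationSpec(
        sources=(
            SourceSpec(shape=ShapeParams(f0=10.0, a_pt=0.2, jitter_sd=0.05),
                       amplitude=3.0),
        ),
        n_channels=8,
        duration=60.0,
        fs=FS,
        chi=1.5,
        noise_amp=1.0,
    )
    return make_recording(spec, seed=0)


@pytest.fixture()
def sinusoid_recording():
    """Noise-free 10 Hz sinusoid on a single channel, 40 s at 250 Hz."""
    t = np.arange(0, 40, 1 / FS)
    return RawRecording(np.cos(2 * np.pi * 10 * t)[None, :], FS, ["c1"])
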