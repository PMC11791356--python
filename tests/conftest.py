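import numpy as np
import pytest

from nirspot import (BaselineParams, MovieGeometry, SensorParams,
                     StimulusProtocol)
from nirspot.dff import DffStack


@pytest.fixture
def sensor():
    """Calibrated transduction constants: Kd 15 uM, saturation 6.44."""
    return SensorParams()


@pytest.fixture
def small_geometry():
    return MovieGeometry(height=16, width=16, n_frames=50)


@pytest.fixture
def small_protocol():
    # 4 s pre-stimulus, 2 s stimulation, inside a 10 s movie
    return StimulusProtocol(stim_start_s=4.0, stim_duration_s=2.0)


def make_dff_stack(dff, frame_rate=5.0, protocol=None, pixel_size=0.74):
    """Wrap a raw dF/F0 array into a DffStack with trivial baseline."""
    dff = np.asarray(dff, dtype=np.float64)
    geometry = MovieGeometry(height=dff.shape[1], width=dff.shape[2],
                             n_frames=dff.shape[0], frame_rate_hz=frame_rate,
                             pixel_size_um=pixel_size)
    return DffStack(dff=dff, baseline=np.ones(dff.shape[1:]),
                    valid=np.ones(dff.shape[1:], dtype=bool),
                    params=BaselineParams(), geometry=geometry,
                    protocol=protocol)


@pytest.fixture
def dff_factory():
    return make_dff_stack
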