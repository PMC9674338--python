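import numpy as np
import pytest

from sacglu import synth, trace_io
from sacglu.release import QuantalWaveform


@pytest.fixture(scope="session")
def quantum():
    return QuantalWaveform()  # 2 ms rise, 30 ms decay, unit amplitude


@pytest.fixture(scope="session")
def small_fov():
    """12 sustained + 12 transient ROIs at generator defaults."""
    rec, truths = synth.synthesize_fov(12, 12, seed=20)
    return rec, truths


@pytest.fixture(scope="session")
def small_fov_dff(small_fov):
    rec, truths = small_fov
    out = trace_io.RecordingSet(
        [trace_io.compute_dff(t) for t in rec],
        frame_rate_hz=rec.frame_rate_hz,
        provenance=rec.provenance,
    )
    return out, truths


def make_dff_trace(
    dff,
    dt=1 / 58.25,
    stim_onset_s=4.0,
    stim_offset_s=6.0,
    roi_id="t",
):
    """Build an ROITrace directly from a ΔF/F array."""
    dff = np.asarray(dff, float)
    return trace_io.ROITrace(
        roi_id=roi_id,
        time_s=np.arange(dff.size) * dt,
        f_raw=100.0 * (1 + dff),
        dff=dff,
        stim_onset_s=stim_onset_s,
        stim_offset_s=stim_offset_s,
    )
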