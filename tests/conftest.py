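import numpy as np
import pytest

from photolock.photometry import PhotometryRecording, ProcessedTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(ch465, ch405, rate_hz=20.0):
    n = len(ch465)
    t = np.arange(n) / rate_hz
    return PhotometryRecording(t, np.asarray(ch465, float), np.asarray(ch405, float), rate_hz)


def trace_from_z(z, rate_hz=20.0):
    """Build a ProcessedTrace around a given z-score array (for detection
    tests where only the z trace matters)."""
    z = np.asarray(z, float)
    n = len(z)
    t = np.arange(n) / rate_hz
    ones = np.ones(n)
    return ProcessedTrace(
        time_s=t,
        dff=z.copy(),
        zscore=z,
        fitted_control=ones,
        baseline_465=ones,
        baseline_405=ones,
        fit_slope=1.0,
        fit_intercept=0.0,
        rate_hz=rate_hz,
        params={"zscore_sd": 1.0, "zscore_mean": 0.0},
    )
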