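import numpy as np
import pytest

from pupilencode import AnalysisConfig, GeometryConfig, SampleSeries

LEFT_X = 530.0  # inside the default model-grid ROI
RIGHT_X = 1440.0
CENTER_Y = 540.0


@pytest.fixture
def geom():
    return GeometryConfig()


@pytest.fixture
def cfg():
    return AnalysisConfig()


def series_from_segments(segments, pupil=2000.0, pid="p01", y=CENTER_Y):
    """Build a 1000-Hz SampleSeries from (duration_ms, 'L'|'R') segments."""
    xs = []
    for dur, side in segments:
        x = LEFT_X if side == "L" else RIGHT_X
        xs.append(np.full(int(dur), x))
    gx = np.concatenate(xs)
    n = len(gx)
    return SampleSeries(
        pid,
        pid,
        np.arange(n),
        gx,
        np.full(n, y),
        np.full(n, float(pupil)),
        np.ones(n, dtype=bool),
    )


@pytest.fixture
def make_series():
    return series_from_segments
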