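import numpy as np
import pytest

from blinklab.detect import DetectionParams
from blinklab.ear import EARTrace, EyeLandmarkSet


@pytest.fixture
def worked_eye() -> EyeLandmarkSet:
    """Open eye whose EAR evaluates to 0.5 by hand."""
    return EyeLandmarkSet(p1=(0, 0), p4=(4, 0), p2=(1, 1), p6=(1, -1), p3=(3, 1), p5=(3, -1))


@pytest.fixture
def default_params() -> DetectionParams:
    return DetectionParams()


@pytest.fixture
def fast_params() -> DetectionParams:
    """Short baseline window so unit tests can use brief traces."""
    return DetectionParams(baseline_window_s=5.0)


def make_trace(values, fps=240.0, side="left", gap_mask=None) -> EARTrace:
    return EARTrace(side=side, fps=fps, values=np.asarray(values, dtype=float), gap_mask=gap_mask)


def triangle_dip_trace(
    fps=240.0,
    duration_s=40.0,
    baseline=0.3,
    dip_centers_s=(),
    dip_depth=0.25,
    total_width_s=0.3125,
):
    """Constant trace with V-shaped (triangular) dips of known geometry.

    A dip reaches ``baseline - dip_depth`` at its centre; the width of the
    region below any level follows from similar triangles, e.g. with the
    defaults the full width at the 0.21 level is 0.64 * total_width_s.
    """
    n = int(round(duration_s * fps))
    t = np.arange(n) / fps
    v = np.full(n, baseline)
    for c in dip_centers_s:
        u = np.abs(t - c) / (total_width_s / 2.0)
        inside = u < 1.0
        v[inside] = np.minimum(v[inside], baseline - dip_depth * (1.0 - u[inside]))
    return make_trace(v, fps=fps)
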