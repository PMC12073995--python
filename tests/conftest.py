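import numpy as np
import pytest

from pvspet import phantom as ph
from pvspet.core import TimeActivityCurve


@pytest.fixture(scope="session")
def tissue48():
    """A 48^3 tissue phantom shared across tests (read-only)."""
    return ph.make_tissue_phantom((48, 48, 48), seed=1)


@pytest.fixture(scope="session")
def frame_grid():
    """Default 55-frame schedule: (mid_times, durations)."""
    starts, durations = ph.default_frame_schedule()
    return starts + durations / 2.0, durations


@pytest.fixture(scope="session")
def reference_tac(frame_grid):
    mid, _ = frame_grid
    terms = ph.reference_curve_terms()
    return TimeActivityCurve(mid, ph.expsum_eval(terms, mid),
                             kind="reference")


def srtm_forward(mid_times, r1, k2, bp, terms=None):
    """Exact SRTM forward solution on a time grid (analytic convolution)."""
    if terms is None:
        terms = ph.reference_curve_terms()
    c_ref = ph.expsum_eval(terms, mid_times)
    k2a = k2 / (1.0 + bp)
    conv = np.atleast_2d(
        ph.expsum_conv_exp(terms, np.array([k2a]), mid_times))[0]
    return r1 * c_ref + (k2 - r1 * k2a) * conv
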