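import numpy as np
import pytest

from hrvreact import NNSegment, RRSeries, SimConfig


def make_segment(values, start_time_s=0.0, **kwargs):
    """Build an NNSegment whose tachogram abscissae follow from the intervals."""
    values = np.asarray(values, dtype=float)
    ends = start_time_s + np.cumsum(values) / 1000.0
    return NNSegment(nn_ms=values, end_times_s=ends, start_time_s=start_time_s,
                     **kwargs)


def make_series(values, labels=None, **kwargs):
    values = np.asarray(values, dtype=float)
    if labels is None:
        labels = np.full(values.size, "normal", dtype="<U8")
    return RRSeries(intervals_ms=values, labels=np.asarray(labels, dtype="<U8"),
                    **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240529)


@pytest.fixture
def small_config():
    """A cohort small enough for fast end-to-end runs but long enough that
    300 NN intervals remain after the 180 s skip in every condition."""
    return SimConfig(n_subjects=6, seed=7, duration_s=600.0)


def random_segments(rng, n_segments, length=300, lo=600.0, hi=1200.0):
    """Random physiological segments for oracle-equivalence checks."""
    for _ in range(n_segments):
        base = rng.uniform(lo, hi)
        vals = np.clip(base + rng.normal(0.0, 60.0, size=length), 320.0, 1900.0)
        yield make_segment(vals)
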