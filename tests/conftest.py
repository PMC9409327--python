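import numpy as np
import pytest

from hrvkit.series import BeatSeries, NNSeries


def make_nn(intervals, start=0.0, contiguous=None, sinus_fraction=1.0):
    """Build an NNSeries directly from an interval list (all contiguous by default)."""
    intervals = np.asarray(intervals, dtype=float)
    end_times = start + np.cumsum(intervals)
    if contiguous is None:
        contiguous = np.ones(intervals.size, dtype=bool)
        if intervals.size:
            contiguous[0] = False
    return NNSeries(intervals, end_times, np.asarray(contiguous, bool), sinus_fraction)


def make_beats(intervals, labels=None):
    """BeatSeries from integer RR intervals (times by cumulative sum from 0)."""
    times = np.concatenate([[0], np.cumsum(np.asarray(intervals, dtype=np.int64))])
    if labels is None:
        labels = ["N"] * times.size
    return BeatSeries(times=times, labels=np.asarray(labels))


@pytest.fixture
def constant_nn():
    return make_nn([1000.0] * 1200)


@pytest.fixture
def rng():
    return np.random.default_rng(20220806)
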