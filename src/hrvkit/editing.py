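"""Beat editing, outlier filtering and the sinus-purity quality gate.

The editing rule removes every interval touching an abnormal beat: an
interval is a valid NN interval only if *both* of its endpoint beats are
sinus (N).  This simultaneously drops intervals ending at an ectopic or
unknown beat and intervals succeeding one (the compensatory-pause interval),
with no interpolation of the removed data.

The moving-window filter then screens each set of five contiguous NN
intervals: the central interval is compared with the mean of its four
neighbours and replaced by that local average when it deviates by more than
20 %.  A single left-to-right pass is made and all comparisons use the
original (pre-pass) values, so a replacement never cascades.

Finally, a recording qualifies for analysis only if more than 95 % of its
beats are pure sinus beats.
"""

from __future__ import annotations

import logging

import numpy as np

from .series import BeatSeries, NNSeries

logger = logging.getLogger(__name__)

#: Window of the moving-average filter (central interval + 4 neighbours).
FILTER_WINDOW = 5


def edit_beats(series: BeatSeries) -> NNSeries:
    """Eliminate abnormal beats and the intervals they touch.

    Parameters
    ----------
    series : BeatSeries
        Labeled beats; at least 2.

    Returns
    -------
    NNSeries
        Retained intervals are exactly the differences of consecutive beat
        times whose both endpoints are labeled N.  Removals are recorded as
        gaps (contiguity flags), never interpolated.  ``sinus_fraction`` is
        the proportion of N beats in the input.
    """
    if len(series) < 2:
        raise ValueError("need at least 2 beats to form an interval")
    is_n = series.labels == "N"
    keep = is_n[:-1] & is_n[1:]  # interval (i, i+1) valid iff both beats sinus
    kept_idx = np.flatnonzero(keep)
    intervals = np.diff(series.times).astype(float)[kept_idx]
    end_times = series.times[1:].astype(float)[kept_idx]
    contiguous = np.zeros(kept_idx.size, dtype=bool)
    if kept_idx.size > 1:
        contiguous[1:] = np.diff(kept_idx) == 1
    if kept_idx.size == 0:
        logger.warning("editing removed every interval (%d beats)", len(series))
    return NNSeries(intervals, end_times, contiguous, series.sinus_fraction)


def filter_outliers(nn: NNSeries, threshold: float = 0.20) -> NNSeries:
    """Replace local outliers by the 4-neighbour local average.

    For every window of five mutually contiguous intervals, the central
    interval is an outlier when it lies strictly outside
    ``[(1-threshold)*avg, (1+threshold)*avg]`` of the local average of the
    other four; a deviation of exactly ``threshold`` is not an outlier.
    Comparisons and replacement values use the original series (single
    pass); windows never span a gap.  Runs shorter than five intervals pass
    through unfiltered.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out = nn.intervals.copy()
    half = FILTER_WINDOW // 2
    for run in nn.runs():
        orig = nn.intervals[run]
        m = orig.size
        if m < FILTER_WINDOW:
            logger.info("run of %d contiguous intervals shorter than filter window; passed through", m)
            continue
        for c in range(half, m - half):
            local = (orig[c - 2] + orig[c - 1] + orig[c + 1] + orig[c + 2]) / 4.0
            if orig[c] > (1.0 + threshold) * local or orig[c] < (1.0 - threshold) * local:
                out[run.start + c] = local
    return NNSeries(out, nn.end_times.copy(), nn.contiguous.copy(), nn.sinus_fraction)


def sinus_gate(series: BeatSeries, threshold: float = 0.95) -> bool:
    """True iff the recording has strictly more than ``threshold`` sinus beats.

    The boundary case (fraction exactly equal to the threshold) fails.
    """
    return series.sinus_fraction > threshold
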