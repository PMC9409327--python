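"""Time-domain and geometric HRV metrics.

All standard deviations are population SDs (ddof=0) unless stated otherwise.
Successive-difference statistics (RMSSD, NNx, pNNx) use only pairs of
temporally adjacent intervals — pairs spanning an edited-out gap are skipped.
Missing statistics (too little data) are reported as ``None``, never as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .series import NNSeries

#: Conventional NN-histogram bin width, 1/128 s in ms.
DEFAULT_BIN_WIDTH = 1000.0 / 128.0


@dataclass
class TimeDomainMetrics:
    """The time-domain panel of a single recording."""

    sdnn: float                 # SD of all NN intervals, ms
    sdann: Optional[float]      # SD of per-segment mean NN, ms
    sdnni: Optional[float]      # mean of per-segment NN SDs, ms
    rmssd: Optional[float]      # RMS of successive NN differences, ms
    nnx: Optional[int]          # count of |successive diff| > x ms
    pnnx: Optional[float]       # nnx / number of adjacent pairs
    mean_hr: float              # mean of 60000/NN, bpm
    sd_hr: float                # SD of 60000/NN, bpm
    hrv_ti: Optional[float] = None   # triangular index
    tinn: Optional[float] = None     # triangular interpolation baseline width, ms

    def to_dict(self) -> dict:
        return asdict(self)


def _segment_stats(nn: NNSeries, segment_s: float, min_partial_s: float = 60.0):
    """Per-segment (mean, SD) of NN intervals, segments aligned to recording start.

    An interval belongs to the segment containing its end time.  A trailing
    partial segment is kept only if it spans at least ``min_partial_s``.
    """
    seg_ms = segment_s * 1000.0
    rel = nn.end_times - nn.start_time
    # interval ending exactly on a boundary belongs to the earlier segment
    idx = np.ceil(rel / seg_ms).astype(int) - 1
    idx[idx < 0] = 0
    n_seg = int(idx.max()) + 1
    total = rel[-1]
    last_span = total - (n_seg - 1) * seg_ms
    means, sds = [], []
    for k in range(n_seg):
        vals = nn.intervals[idx == k]
        if vals.size == 0:
            continue
        if k == n_seg - 1 and last_span < min_partial_s * 1000.0 and n_seg > 1:
            continue
        means.append(float(np.mean(vals)))
        sds.append(float(np.std(vals)))
    return means, sds


def time_domain_metrics(
    nn: NNSeries,
    x_ms: float = 50.0,
    segment_s: float = 300.0,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> TimeDomainMetrics:
    """Compute the full time-domain panel, including the geometric measures.

    Parameters
    ----------
    nn : NNSeries
        Edited NN intervals (at least 2).
    x_ms : float
        Threshold of the NNx / pNNx count (default 50 ms, i.e. NN50/pNN50).
    segment_s : float
        Segment length for SDANN / SDNN-index (default 5 min).
    bin_width : float
        Histogram bin for the triangular index and TINN (default 1/128 s).
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 intervals")
    iv = nn.intervals
    sdnn = float(np.std(iv))

    means, sds = _segment_stats(nn, segment_s)
    sdann = float(np.std(means)) if len(means) >= 2 else None
    sdnni = float(np.mean(sds)) if len(sds) >= 1 else None

    d = nn.successive_differences()
    if d.size:
        rmssd = float(np.sqrt(np.mean(d**2)))
        nnx = int(np.sum(np.abs(d) > x_ms))
        pnnx = nnx / d.size
    else:
        rmssd = nnx = pnnx = None

    hr = 60000.0 / iv
    ti, tinn = geometric_metrics(nn, bin_width=bin_width)
    return TimeDomainMetrics(
        sdnn=sdnn, sdann=sdann, sdnni=sdnni, rmssd=rmssd, nnx=nnx, pnnx=pnnx,
        mean_hr=float(np.mean(hr)), sd_hr=float(np.std(hr)),
        hrv_ti=ti, tinn=tinn,
    )


def geometric_metrics(nn: NNSeries, bin_width: float = DEFAULT_BIN_WIDTH):
    """Triangular index and TINN from the NN-interval histogram.

    The histogram uses bins of ``bin_width`` ms aligned to multiples of the
    bin width.  The triangular index is the total interval count divided by
    the modal bin height.  TINN is the baseline width ``M - N`` of the
    least-squares triangle fitted to the histogram with its apex fixed at
    the modal bin; a single-bin histogram degenerates to
    ``(1.0, bin_width)``.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 intervals")
    iv = nn.intervals
    lo = int(np.floor(iv.min() / bin_width))
    hi = int(np.floor(iv.max() / bin_width))
    counts = np.bincount((np.floor(iv / bin_width).astype(int) - lo), minlength=hi - lo + 1).astype(float)
    hrv_ti = float(iv.size / counts.max())
    if np.count_nonzero(counts) == 1:
        return hrv_ti, float(bin_width)

    # pad one empty bin each side so the triangle may touch zero beyond the data
    counts = np.concatenate(([0.0], counts, [0.0]))
    centers = (np.arange(counts.size) + lo - 1 + 0.5) * bin_width
    mode = int(np.argmax(counts))
    height = counts[mode]

    best = (np.inf, bin_width)
    for i in range(0, mode):            # left baseline bin N
        for j in range(mode + 1, counts.size):  # right baseline bin M
            tri = np.zeros_like(counts)
            left = slice(i, mode + 1)
            tri[left] = height * (centers[left] - centers[i]) / (centers[mode] - centers[i])
            right = slice(mode, j + 1)
            tri[right] = height * (centers[j] - centers[right]) / (centers[j] - centers[mode])
            tri[mode] = height
            err = float(np.sum((counts - tri) ** 2))
            if err < best[0]:
                best = (err, float(centers[j] - centers[i]))
    return hrv_ti, best[1]
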