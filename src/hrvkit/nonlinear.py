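"""Non-linear HRV metrics: Poincaré SD1/SD2, sample entropy, DFA exponents.

Poincaré pairs are taken only across temporally adjacent intervals; sample
entropy and detrended fluctuation analysis operate on the concatenated
interval list (gaps are rare after the sinus-purity gate — a documented
approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .series import NNSeries

logger = logging.getLogger(__name__)

ALPHA1_BOXES = (4, 11)   # short-term DFA box range, beats
ALPHA2_BOXES = (12, 64)  # long-term DFA box range, beats


@dataclass
class NonlinearMetrics:
    """The non-linear panel of a single recording."""

    sd1: Optional[float]      # ms, dispersion perpendicular to identity line
    sd2: Optional[float]      # ms, dispersion along identity line
    sampen: Optional[float]   # nats
    alpha1: Optional[float]   # short-term DFA scaling exponent
    alpha2: Optional[float]   # long-term DFA scaling exponent

    def to_dict(self) -> dict:
        return asdict(self)


def _as_values(x: Union[NNSeries, Sequence[float]]) -> np.ndarray:
    if isinstance(x, NNSeries):
        return np.asarray(x.intervals, dtype=float)
    return np.asarray(x, dtype=float)


def poincare(nn: NNSeries) -> Tuple[Optional[float], Optional[float]]:
    """SD1/SD2 of the lag-1 return map, over adjacent interval pairs only.

    SD1 is the population SD of ``(x[j+1] - x[j]) / sqrt(2)`` (spread
    perpendicular to the line of identity), SD2 of
    ``(x[j+1] + x[j]) / sqrt(2)`` (spread along it).
    """
    j = nn.pair_indices()
    if j.size < 2:
        logger.warning("fewer than 2 adjacent interval pairs; Poincaré SD1/SD2 missing")
        return None, None
    x1 = nn.intervals[j]
    x2 = nn.intervals[j + 1]
    sd1 = float(np.std((x2 - x1) / np.sqrt(2.0)))
    sd2 = float(np.std((x2 + x1) / np.sqrt(2.0)))
    return sd1, sd2


def sample_entropy(
    x: Union[NNSeries, Sequence[float]],
    m: int = 2,
    r: Optional[float] = None,
) -> Optional[float]:
    """Sample entropy −ln(A/B) with Chebyshev template distance.

    ``B`` counts ordered pairs of distinct length-``m`` templates matching
    within tolerance ``r``; ``A`` the same at length ``m+1``.  Self-matches
    are excluded.  ``r`` defaults to 0.2 times the population SD of the
    series.  Returns None (missing) when either count is zero.
    """
    v = _as_values(x)
    n = v.size
    if n < m + 2:
        raise ValueError(f"need at least m+2={m + 2} values")
    if r is None:
        r = 0.2 * float(np.std(v))
    if r < 0:
        raise ValueError("tolerance r must be non-negative")

    nt = n - m  # number of templates, same count for lengths m and m+1
    # within[k][i, j] == True iff |v[i+k] - v[j+k]| <= r
    close = np.abs(v[:, None] - v[None, :]) <= r
    match_m = np.ones((nt, nt), dtype=bool)
    for k in range(m):
        match_m &= close[k:k + nt, k:k + nt]
    match_m1 = match_m & close[m:m + nt, m:m + nt]

    iu = np.triu_indices(nt, k=1)
    b = int(np.count_nonzero(match_m[iu]))
    a = int(np.count_nonzero(match_m1[iu]))
    if a == 0 or b == 0:
        logger.warning("sample entropy undefined (A=%d, B=%d); reported missing", a, b)
        return None
    return float(-np.log(a / b))


def dfa(
    x: Union[NNSeries, Sequence[float]],
    short_boxes: Tuple[int, int] = ALPHA1_BOXES,
    long_boxes: Tuple[int, int] = ALPHA2_BOXES,
) -> Tuple[Optional[float], Optional[float]]:
    """Detrended fluctuation analysis scaling exponents (alpha1, alpha2).

    The mean-centered series is integrated; for each box size ``n`` the
    profile is split into ``N // n`` non-overlapping boxes (tail discarded),
    each box is linearly detrended by least squares, and ``F(n)`` is the RMS
    residual.  Each exponent is the slope of ``log F(n)`` against ``log n``
    over its box range.  alpha1 requires ≥ 100 intervals, alpha2 ≥ 300;
    otherwise the exponent is missing.
    """
    v = _as_values(x)
    n_total = v.size
    profile = np.cumsum(v - np.mean(v))

    def fluctuation(box: int) -> float:
        nb = n_total // box
        segs = profile[: nb * box].reshape(nb, box)
        t = np.arange(box, dtype=float)
        t_c = t - t.mean()
        denom = np.sum(t_c**2)
        y_mean = segs.mean(axis=1, keepdims=True)
        slope = (segs @ t_c) / denom
        resid = segs - y_mean - slope[:, None] * t_c
        return float(np.sqrt(np.mean(resid**2)))

    def exponent(lo: int, hi: int) -> Optional[float]:
        sizes = np.arange(lo, hi + 1)
        f = np.array([fluctuation(int(s)) for s in sizes])
        good = f > 0
        if np.count_nonzero(good) < 2:  # e.g. a constant series has zero fluctuation
            return None
        return float(np.polyfit(np.log(sizes[good]), np.log(f[good]), 1)[0])

    alpha1 = exponent(*short_boxes) if n_total >= 100 else None
    alpha2 = exponent(*long_boxes) if n_total >= 300 else None
    if alpha1 is None or alpha2 is None:
        logger.info("DFA exponents missing for series of %d intervals", n_total)
    if alpha1 is not None and not 0.3 <= alpha1 <= 1.7:
        logger.warning("alpha1=%.3f outside the usual physiological range [0.3, 1.7]", alpha1)
    return alpha1, alpha2


def nonlinear_metrics(
    nn: NNSeries,
    m: int = 2,
    r: Optional[float] = None,
    short_boxes: Tuple[int, int] = ALPHA1_BOXES,
    long_boxes: Tuple[int, int] = ALPHA2_BOXES,
) -> NonlinearMetrics:
    """Compute the full non-linear panel."""
    sd1, sd2 = poincare(nn)
    sampen = sample_entropy(nn, m=m, r=r) if len(nn) >= m + 2 else None
    alpha1, alpha2 = dfa(nn, short_boxes=short_boxes, long_boxes=long_boxes)
    return NonlinearMetrics(sd1=sd1, sd2=sd2, sampen=sampen, alpha1=alpha1, alpha2=alpha2)
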