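"""Welch-method frequency-domain HRV metrics.

The unevenly spaced NN series is resampled onto a uniform grid by cubic
spline (4 Hz default), and the power spectral density is estimated with
Welch's method: 256 s segments, 50 % overlap, Hann window, per-segment
linear detrend, one-sided density normalised so that its integral over
frequency recovers the time-domain variance.

Band powers integrate the density over the conventional bands
VLF [0.0033, 0.04) Hz, LF [0.04, 0.15) Hz and HF [0.15, 0.40] Hz using a
rectangle rule on the Welch frequency grid, so the three bands partition
total power exactly and nLF + nHF = 1 by construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import welch

from .series import NNSeries

logger = logging.getLogger(__name__)

VLF_BAND: Tuple[float, float] = (0.0033, 0.04)
LF_BAND: Tuple[float, float] = (0.04, 0.15)
HF_BAND: Tuple[float, float] = (0.15, 0.40)

#: Minimum recording span (s) for a meaningful 0.04 Hz resolution.
MIN_SPAN_S = 120.0


@dataclass
class Tachogram:
    """Evenly resampled NN series (ms values at fs Hz)."""

    values: np.ndarray
    fs: float
    t0: float = 0.0  # time of the first sample, s

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 2 * HF_BAND[1]:
            raise ValueError("sampling rate must exceed twice the HF upper edge (0.8 Hz)")


@dataclass
class PSD:
    """One-sided power spectral density, ms^2/Hz on a uniform grid."""

    freqs: np.ndarray
    density: np.ndarray

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


@dataclass
class SpectralMetrics:
    """The frequency-domain panel of a single recording."""

    tp: float        # total power VLF+LF+HF, ms^2
    vlf: float
    lf: float
    hf: float
    n_lf: Optional[float]    # LF/(LF+HF)
    n_hf: Optional[float]    # HF/(LF+HF)
    lf_hf: Optional[float]   # LF/HF ratio; None when HF power is zero
    peak_vlf: float
    peak_lf: float
    peak_hf: float

    def to_dict(self) -> dict:
        return asdict(self)


def resample_nn(nn: NNSeries, fs: float = 4.0) -> Tachogram:
    """Cubic-spline resampling of (end_time, interval) pairs onto a uniform grid.

    Gaps left by editing are bridged by the spline.  Raises for recordings
    spanning less than 120 s.
    """
    if len(nn) < 2:
        raise ValueError("need at least 2 intervals to resample")
    t = nn.end_times / 1000.0  # s
    span = t[-1] - t[0]
    if span < MIN_SPAN_S:
        raise ValueError(f"recording span {span:.1f} s is too short (< {MIN_SPAN_S:.0f} s)")
    spline = CubicSpline(t, nn.intervals)
    n = int(span * fs)
    grid = t[0] + np.arange(n) / fs
    return Tachogram(values=spline(grid), fs=fs, t0=float(t[0]))


def welch_psd(tach: Tachogram, segment_s: float = 256.0, overlap: float = 0.5) -> PSD:
    """Welch PSD: Hann window, per-segment linear detrend, 50 % overlap."""
    if not 0 <= overlap < 1:
        raise ValueError("overlap must be in [0, 1)")
    nperseg = int(round(segment_s * tach.fs))
    if tach.values.size < nperseg:
        warnings.warn(
            "tachogram shorter than one Welch segment; falling back to a single-segment periodogram",
            stacklevel=2,
        )
        nperseg = tach.values.size
    freqs, density = welch(
        tach.values,
        fs=tach.fs,
        window="hann",
        nperseg=nperseg,
        noverlap=int(nperseg * overlap),
        detrend="linear",
        scaling="density",
    )
    return PSD(freqs=freqs, density=density)


def _band_mask(freqs: np.ndarray, lo: float, hi: float, closed_hi: bool) -> np.ndarray:
    if closed_hi:
        return (freqs >= lo) & (freqs <= hi)
    return (freqs >= lo) & (freqs < hi)


def band_powers(psd: PSD) -> SpectralMetrics:
    """Integrate the PSD over the VLF/LF/HF bands and locate band peaks.

    Band edges are half-open ``[lo, hi)`` with the HF band closed at
    0.40 Hz, so no frequency bin is counted twice and the three powers sum
    to total power exactly.
    """
    if psd.freqs[-1] < HF_BAND[1]:
        raise ValueError("PSD does not cover the HF band up to 0.40 Hz")
    df = psd.df

    powers, peaks = {}, {}
    for name, (lo, hi), closed in (
        ("vlf", VLF_BAND, False),
        ("lf", LF_BAND, False),
        ("hf", HF_BAND, True),
    ):
        mask = _band_mask(psd.freqs, lo, hi, closed)
        powers[name] = float(np.sum(psd.density[mask]) * df)
        band_f = psd.freqs[mask]
        band_d = psd.density[mask]
        peaks[name] = float(band_f[np.argmax(band_d)]) if band_f.size else float("nan")

    lf, hf, vlf = powers["lf"], powers["hf"], powers["vlf"]
    denom = lf + hf
    if hf > 0:
        lf_hf = lf / hf
    else:
        logger.warning("HF power is zero; LF/HF reported as missing")
        lf_hf = None
    return SpectralMetrics(
        tp=vlf + lf + hf, vlf=vlf, lf=lf, hf=hf,
        n_lf=lf / denom if denom > 0 else None,
        n_hf=hf / denom if denom > 0 else None,
        lf_hf=lf_hf,
        peak_vlf=peaks["vlf"], peak_lf=peaks["lf"], peak_hf=peaks["hf"],
    )


def spectral_metrics(nn: NNSeries, fs: float = 4.0, segment_s: float = 256.0,
                     overlap: float = 0.5) -> SpectralMetrics:
    """Convenience composition: resample → Welch → band powers."""
    return band_powers(welch_psd(resample_nn(nn, fs=fs), segment_s=segment_s, overlap=overlap))
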