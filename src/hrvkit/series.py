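"""Core containers: beat-annotated event series and edited NN-interval series.

A recording enters the pipeline as a :class:`BeatSeries` — beat times in
milliseconds with one label per beat (``N`` sinus, ``V`` ventricular ectopic,
``S`` supraventricular ectopic, ``U`` unknown).  Editing converts it into an
:class:`NNSeries` of normal-to-normal intervals.  Removed beats leave *gaps*;
gaps are represented via per-interval contiguity flags and are never filled
by interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

VALID_LABELS = frozenset("NVSU")


@dataclass
class BeatSeries:
    """Time-stamped, labeled heartbeats.

    Parameters
    ----------
    times : array of int
        Beat times in ms, strictly increasing, 1 ms resolution.
    labels : array of str
        One of ``N``, ``V``, ``S``, ``U`` per beat.
    """

    times: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype="<U1")
        if self.times.ndim != 1 or self.labels.shape != self.times.shape:
            raise ValueError("times and labels must be 1-D arrays of equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0]) + 1
            raise ValueError(f"beat times must be strictly increasing (violated at beat {bad})")
        unknown = set(np.unique(self.labels)) - VALID_LABELS
        if unknown:
            raise ValueError(f"unknown beat labels: {sorted(unknown)!r}")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def sinus_fraction(self) -> float:
        """Proportion of beats labeled N."""
        if len(self) == 0:
            return float("nan")
        return float(np.mean(self.labels == "N"))

    @property
    def duration_ms(self) -> int:
        """Span from first to last beat, ms."""
        if len(self) < 2:
            return 0
        return int(self.times[-1] - self.times[0])


@dataclass
class NNSeries:
    """Edited normal-to-normal intervals with gap bookkeeping.

    ``contiguous[j]`` is True iff interval ``j-1`` is the immediate temporal
    neighbour of interval ``j`` (no edited-out beats between them); the first
    interval's flag is always False.  Statistics over successive differences
    (RMSSD, Poincaré pairs, ...) must only use pairs ``(j, j+1)`` with
    ``contiguous[j+1]`` set.
    """

    intervals: np.ndarray
    end_times: np.ndarray
    contiguous: np.ndarray
    sinus_fraction: float

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        self.end_times = np.asarray(self.end_times, dtype=float)
        self.contiguous = np.asarray(self.contiguous, dtype=bool)
        n = self.intervals.size
        if self.end_times.size != n or self.contiguous.size != n:
            raise ValueError("intervals, end_times and contiguous must have equal length")
        if n and np.any(self.intervals <= 0):
            raise ValueError("all NN intervals must be positive")
        if n > 1 and np.any(np.diff(self.end_times) <= 0):
            raise ValueError("interval end times must be strictly increasing")
        if n and self.contiguous[0]:
            raise ValueError("first interval cannot be flagged contiguous")

    def __len__(self) -> int:
        return int(self.intervals.size)

    @property
    def start_time(self) -> float:
        """Time of the beat opening the first interval, ms."""
        if len(self) == 0:
            raise ValueError("empty NN series")
        return float(self.end_times[0] - self.intervals[0])

    def pair_indices(self) -> np.ndarray:
        """Indices j such that intervals (j, j+1) are temporally adjacent."""
        if len(self) < 2:
            return np.empty(0, dtype=np.intp)
        return np.flatnonzero(self.contiguous[1:])

    def successive_differences(self) -> np.ndarray:
        """intervals[j+1] - intervals[j] over adjacent pairs only."""
        j = self.pair_indices()
        return self.intervals[j + 1] - self.intervals[j]

    def runs(self) -> Iterator[slice]:
        """Maximal stretches of mutually contiguous intervals, as slices."""
        n = len(self)
        if n == 0:
            return
        starts = np.flatnonzero(~self.contiguous)
        bounds = np.append(starts, n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            yield slice(int(a), int(b))
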