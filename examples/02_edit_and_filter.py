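"""Beat editing and outlier filtering on a small hand-readable series.

Editing removes every interval touching a non-sinus beat: the interval
ending at the ectopic AND the interval that follows it (no interpolation —
the removal leaves a gap).  The moving-window filter then screens each set
of five contiguous NN intervals and replaces a central value deviating more
than 20% from the average of its four neighbours.
"""

import numpy as np

from hrvkit import BeatSeries, edit_beats, filter_outliers, sinus_gate
from hrvkit.series import NNSeries

times = np.cumsum([0, 800, 820, 600, 1000, 810, 805, 795, 790])
labels = list("NNVNNNNNN")
beats = BeatSeries(times=times, labels=labels)

nn = edit_beats(beats)
print("labels:        ", "".join(labels))
print("kept intervals:", nn.intervals.tolist())
print("contiguous:    ", nn.contiguous.tolist())
print(f"sinus fraction: {nn.sinus_fraction:.3f} -> gate "
      f"{'passes' if sinus_gate(beats) else 'fails'} (needs > 0.95)")

# a 1200 ms spike inside a contiguous run of five gets replaced by the
# local average of its four neighbours (802.5 ms here)
spiky = NNSeries(
    intervals=[800, 810, 1200, 805, 795],
    end_times=np.cumsum([800, 810, 1200, 805, 795]),
    contiguous=[False, True, True, True, True],
    sinus_fraction=1.0,
)
print("filtered:", filter_outliers(spiky).intervals.tolist())
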