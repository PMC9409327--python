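"""Reading and writing beat annotations, manifests and metric panels.

Beat-annotation CSV: header ``time_ms,label`` with label in {N, V, S, U},
one row per beat.  Bare RR text files (one integer interval in ms per line,
no header) are accepted as a fallback and converted to all-sinus beat times
by cumulative sum.  Cohort manifest CSV:
``subject_id,arm,age,pre_file,post_file``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pandas as pd

from .series import BeatSeries, VALID_LABELS

PathLike = Union[str, Path]

BEAT_HEADER = ["time_ms", "label"]
MANIFEST_HEADER = ["subject_id", "arm", "age", "pre_file", "post_file"]

#: Column orders of the per-recording CSV panels, mirroring the trial tables.
TIME_DOMAIN_ORDER = ["sdnn", "sdann", "nnx", "pnnx", "rmssd", "sdnni",
                     "mean_hr", "sd_hr", "hrv_ti", "tinn"]
SPECTRAL_ORDER = ["tp", "vlf", "lf", "hf", "n_lf", "n_hf", "lf_hf",
                  "peak_vlf", "peak_lf", "peak_hf"]
NONLINEAR_ORDER = ["sd1", "sd2", "sampen", "alpha1", "alpha2"]


def read_beat_csv(path: PathLike) -> BeatSeries:
    """Read a beat-annotation CSV, or a bare RR text file as a fallback.

    Raises with the offending line number on duplicate/decreasing times and
    with the offending token on unknown labels.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first.replace(" ", "") != "time_ms,label":
        return _read_rr_text(path)
    df = pd.read_csv(path, dtype={"time_ms": np.int64, "label": str})
    labels = df["label"].astype(str).to_numpy()
    bad = [l for l in np.unique(labels) if l not in VALID_LABELS]
    if bad:
        raise ValueError(f"{path}: unknown beat label {bad[0]!r}")
    times = df["time_ms"].to_numpy()
    dec = np.flatnonzero(np.diff(times) <= 0)
    if dec.size:
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(f"{path}: non-increasing time at line {int(dec[0]) + 3}")
    return BeatSeries(times=times, labels=labels)


def _read_rr_text(path: Path) -> BeatSeries:
    """One RR interval (ms, integer) per line → all-sinus beats by cumulative sum."""
    rr = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.strip()
            if not tok:
                continue
            try:
                rr.append(int(tok))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: not an integer RR value: {tok!r}") from exc
    if not rr:
        raise ValueError(f"{path}: empty RR file")
    times = np.concatenate([[0], np.cumsum(rr)])
    return BeatSeries(times=times, labels=np.full(times.size, "N", dtype="<U1"))


def write_beat_csv(series: BeatSeries, path: PathLike) -> None:
    df = pd.DataFrame({"time_ms": series.times, "label": series.labels})
    df.to_csv(path, index=False)


def write_manifest(rows: List[Dict], path: PathLike) -> None:
    pd.DataFrame(rows, columns=MANIFEST_HEADER).to_csv(path, index=False)


def read_manifest(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_HEADER) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    return df


def panels_to_json(panels: Dict[str, Dict], path: PathLike) -> None:
    """Serialize metric panels (plus any QC info) deterministically."""
    with open(path, "w") as fh:
        json.dump(panels, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def panels_to_csv_row(panels: Dict[str, Dict]) -> pd.DataFrame:
    """One-row frame in trial-table column order (time, spectral, nonlinear)."""
    row = {}
    for block, order in (("time_domain", TIME_DOMAIN_ORDER),
                         ("spectral", SPECTRAL_ORDER),
                         ("nonlinear", NONLINEAR_ORDER)):
        metrics = panels.get(block, {})
        for key in order:
            row[key] = metrics.get(key)
    return pd.DataFrame([row])
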