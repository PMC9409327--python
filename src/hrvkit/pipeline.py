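"""End-to-end recording analysis: edit → filter → gate → metric panels."""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

from .config import PipelineConfig
from .editing import edit_beats, filter_outliers, sinus_gate
from .frequency import band_powers, resample_nn, welch_psd
from .nonlinear import nonlinear_metrics
from .series import BeatSeries, NNSeries
from .timedomain import time_domain_metrics


def clean_nn(series: BeatSeries, config: Optional[PipelineConfig] = None) -> NNSeries:
    """Editing + outlier filtering (no quality gate)."""
    config = config or PipelineConfig()
    return filter_outliers(edit_beats(series), threshold=config.filter_threshold)


def analyze_recording(series: BeatSeries, config: Optional[PipelineConfig] = None) -> Dict:
    """Full per-recording analysis.

    Returns a dict with ``qc`` (sinus fraction, gate verdict) and — when the
    gate passes — the ``time_domain``, ``spectral`` and ``nonlinear`` metric
    panels.  Recordings failing the >95 % sinus-purity gate get a QC record
    only, with no metric panels.
    """
    config = config or PipelineConfig()
    passed = sinus_gate(series, threshold=config.sinus_threshold)
    out: Dict = {
        "qc": {
            "n_beats": len(series),
            "sinus_fraction": series.sinus_fraction,
            "gate_passed": bool(passed),
        }
    }
    if not passed:
        return out
    nn = clean_nn(series, config)
    td = time_domain_metrics(
        nn, x_ms=config.nnx_threshold_ms, segment_s=config.segment_s,
        bin_width=config.bin_width_ms,
    )
    psd = welch_psd(
        resample_nn(nn, fs=config.resample_fs),
        segment_s=config.welch_segment_s, overlap=config.welch_overlap,
    )
    spec = band_powers(psd)
    r = config.sampen_r_factor * float(np.std(nn.intervals))
    nl = nonlinear_metrics(
        nn, m=config.sampen_m, r=r,
        short_boxes=config.dfa_short, long_boxes=config.dfa_long,
    )
    out["time_domain"] = td.to_dict()
    out["spectral"] = spec.to_dict()
    out["nonlinear"] = nl.to_dict()
    return out
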