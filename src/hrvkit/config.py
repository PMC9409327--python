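"""Single validated configuration document for the whole pipeline.

Every tunable of every stage lives here; nothing downstream has hidden
defaults outside this schema.  Configs round-trip through YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Tuple

import yaml


@dataclass
class PipelineConfig:
    # editing
    filter_threshold: float = 0.20      # moving-window outlier band, fraction of local avg
    sinus_threshold: float = 0.95       # sinus-purity gate (strict >)
    # time domain
    nnx_threshold_ms: float = 50.0      # x of NNx / pNNx
    segment_s: float = 300.0            # SDANN / SDNN-index segment
    bin_width_ms: float = 1000.0 / 128  # geometric histogram bin
    # frequency domain
    resample_fs: float = 4.0
    welch_segment_s: float = 256.0
    welch_overlap: float = 0.5
    # nonlinear
    sampen_m: int = 2
    sampen_r_factor: float = 0.2        # r = factor * SD of the NN series
    dfa_short: Tuple[int, int] = (4, 11)
    dfa_long: Tuple[int, int] = (12, 64)
    # randomness
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 < self.filter_threshold < 1:
            raise ValueError("filter_threshold must be in (0, 1)")
        if not 0 < self.sinus_threshold < 1:
            raise ValueError("sinus_threshold must be in (0, 1)")
        if self.nnx_threshold_ms < 0 or self.segment_s <= 0 or self.bin_width_ms <= 0:
            raise ValueError("nnx_threshold_ms, segment_s and bin_width_ms must be positive")
        if self.resample_fs <= 0.8:
            raise ValueError("resample_fs must exceed 0.8 Hz (Nyquist for the HF band)")
        if not 0 <= self.welch_overlap < 1:
            raise ValueError("welch_overlap must be in [0, 1)")
        if self.sampen_m < 1 or self.sampen_r_factor <= 0:
            raise ValueError("sampen_m must be >= 1 and sampen_r_factor > 0")
        self.dfa_short = tuple(self.dfa_short)
        self.dfa_long = tuple(self.dfa_long)
        for lo, hi in (self.dfa_short, self.dfa_long):
            if lo < 3 or hi <= lo:
                raise ValueError("DFA box ranges must satisfy 3 <= lo < hi")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dfa_short"] = list(self.dfa_short)
        d["dfa_long"] = list(self.dfa_long)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
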