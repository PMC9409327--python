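"""Synthetic RR-interval recordings and three-arm pre/post cohorts.

No patient recordings are distributed with this package, so every pipeline
stage is exercised against simulated 20-minute resting recordings: the
interval (tachogram) domain carries two sinusoidal autonomic modulations —
one inside the LF band (default 0.1 Hz, baroreflex-like) and one inside the
HF band (default 0.25 Hz, respiratory) — plus white Gaussian noise, with
beat times accumulated and quantized to the 1 ms timing resolution of a
high-resolution ECG.  Ectopic beats (premature, optionally with a full
compensatory pause) can be injected and relabeled V/S for testing the
editing rules.

The cohort generator emulates a three-arm (land / water / control) pre-post
exercise trial: per-arm ages, subject-level log-normal heterogeneity on the
modulation amplitudes, and arm-specific post-intervention multipliers.  The
default effect direction follows the aquatic arm of the trial design this
emulates: LF modulation up, HF modulation down (raising LF/HF and the
short-term DFA exponent) and mean heart rate up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from .series import BeatSeries

ARMS = ("land", "water", "control")


@dataclass
class RRGenParams:
    """Parameters of one simulated RR recording.

    Amplitudes and noise in ms; the modulation frequencies must lie inside
    the LF band [0.04, 0.15) and HF band [0.15, 0.40] respectively.
    """

    mean_rr: float = 940.0
    lf_amp: float = 32.0
    lf_freq: float = 0.1
    hf_amp: float = 15.0
    hf_freq: float = 0.25
    noise_sd: float = 25.0
    duration: float = 1200.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if min(self.lf_amp, self.hf_amp, self.noise_sd) < 0:
            raise ValueError("amplitudes and noise_sd must be non-negative")
        if not 0.04 <= self.lf_freq < 0.15:
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15)")
        if not 0.15 <= self.hf_freq <= 0.40:
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.40]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class EctopyParams:
    """Controls for injecting premature ectopic beats."""

    ectopic_fraction: float = 0.03
    label_mix: Dict[str, float] = field(default_factory=lambda: {"V": 1.0, "S": 0.0})
    prematurity: float = 0.5      # fraction of the local RR the beat is advanced
    compensatory: bool = True     # full compensatory pause (next beat on schedule)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if not 0 <= self.ectopic_fraction < 0.5:
            raise ValueError("ectopic_fraction must be in [0, 0.5)")
        if set(self.label_mix) - {"V", "S"}:
            raise ValueError("label_mix keys must be among {'V', 'S'}")
        if abs(sum(self.label_mix.values()) - 1.0) > 1e-9:
            raise ValueError("label_mix must sum to 1")
        if not 0 < self.prematurity < 1:
            raise ValueError("prematurity must be in (0, 1)")


@dataclass
class CohortConfig:
    """A three-arm pre/post cohort (sizes default to 30 land / 29 water / 30 control)."""

    n_per_arm: Tuple[int, int, int] = (30, 29, 30)      # land, water, control
    age_mean_sd: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "land": (62.4, 7.6), "water": (56.7, 8.4), "control": (60.6, 8.3)
        }
    )
    pre_params: Dict[str, RRGenParams] = field(
        default_factory=lambda: {arm: RRGenParams() for arm in ARMS}
    )
    post_multipliers: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            "land": {"lf_amp": 1.0, "hf_amp": 1.0, "mean_rr": 1.0},
            "water": {"lf_amp": 1.3, "hf_amp": 0.8, "mean_rr": 0.94},
            "control": {"lf_amp": 1.0, "hf_amp": 1.0, "mean_rr": 1.0},
        }
    )
    subject_amp_sigma: float = 0.2    # log-normal sigma on per-subject amplitudes
    subject_rr_sigma: float = 0.05    # log-normal sigma on per-subject mean RR
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if any(n < 2 for n in self.n_per_arm):
            raise ValueError("each arm needs at least 2 subjects")
        for arm, mult in self.post_multipliers.items():
            if any(v <= 0 for v in mult.values()):
                raise ValueError(f"post multipliers for arm {arm!r} must be positive")


@dataclass
class CohortSubject:
    """One simulated participant: arm, age and the pre/post recordings."""

    subject_id: str
    arm: str
    age: float
    pre: BeatSeries
    post: BeatSeries


def generate_rr_series(params: RRGenParams, rng: Optional[np.random.Generator] = None) -> BeatSeries:
    """Generate an all-sinus BeatSeries with sinusoidal LF/HF modulation.

    The i-th interval is
    ``mean_rr + lf_amp*sin(2π lf_freq t_i) + hf_amp*sin(2π hf_freq t_i) + ε_i``
    with ``t_i`` the cumulative time of the preceding beat and
    ``ε_i ~ N(0, noise_sd²)``.  Beats accumulate until the span reaches
    ``duration``; cumulative times are then quantized to 1 ms so rounding
    errors do not accumulate.  Raises if any generated interval is ≤ 0.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    t = 0.0  # s
    times = [0.0]
    two_pi = 2.0 * np.pi
    while t < params.duration:
        rr = (
            params.mean_rr
            + params.lf_amp * np.sin(two_pi * params.lf_freq * t)
            + params.hf_amp * np.sin(two_pi * params.hf_freq * t)
        )
        if params.noise_sd > 0:
            rr += rng.normal(0.0, params.noise_sd)
        if rr < 1.0:  # 1 ms timing resolution: also traps the asymptotic stall at rr -> 0+
            raise ValueError(
                "generated a non-positive (sub-millisecond) interval; "
                "modulation amplitudes/noise too large for mean_rr"
            )
        t += rr / 1000.0
        times.append(t * 1000.0)
    times_ms = np.rint(np.asarray(times)).astype(np.int64)
    if np.any(np.diff(times_ms) <= 0):
        raise ValueError("1 ms quantization collapsed consecutive beats; intervals too short")
    labels = np.full(times_ms.size, "N", dtype="<U1")
    return BeatSeries(times=times_ms, labels=labels)


def inject_ectopy(series: BeatSeries, params: EctopyParams,
                  rng: Optional[np.random.Generator] = None) -> BeatSeries:
    """Relabel a fraction of beats as ectopic and advance the V beats.

    ``round(ectopic_fraction * n)`` beats are drawn uniformly without
    replacement, excluding the first and last two beats.  Each V beat is
    moved earlier by ``prematurity`` times its preceding RR interval; with a
    full compensatory pause the following beat stays on schedule, otherwise
    it is advanced by the same shift.  Beat count and time ordering are
    preserved (violations raise).
    """
    if np.any(series.labels != "N"):
        raise ValueError("input series must be all-sinus")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = len(series)
    k = int(round(params.ectopic_fraction * n))
    if k == 0:
        return BeatSeries(series.times.copy(), series.labels.copy())
    candidates = np.arange(2, n - 2)
    if k > candidates.size:
        raise ValueError("too many ectopics requested for this series length")
    chosen = np.sort(rng.choice(candidates, size=k, replace=False))
    labels = series.labels.copy()
    p_v = params.label_mix.get("V", 0.0)
    is_v = rng.random(k) < p_v
    labels[chosen] = np.where(is_v, "V", "S")

    times = series.times.astype(float)
    for idx, v_flag in zip(chosen, is_v):
        if not v_flag:
            continue
        local_rr = times[idx] - times[idx - 1]
        shift = params.prematurity * local_rr
        times[idx] -= shift
        if not params.compensatory:
            times[idx + 1] -= shift
    times = np.rint(times).astype(np.int64)
    if np.any(np.diff(times) <= 0):
        raise ValueError("prematurity shift violated time monotonicity")
    return BeatSeries(times=times, labels=labels)


def generate_cohort(config: CohortConfig,
                    rng: Optional[np.random.Generator] = None) -> List[CohortSubject]:
    """Simulate the full three-arm pre/post cohort.

    Subject-level heterogeneity: log-normal multipliers (``subject_amp_sigma``)
    on both modulation amplitudes and (``subject_rr_sigma``) on mean RR,
    shared between a subject's pre and post recordings so that pre/post
    differences reflect only the arm's post multipliers plus recording noise.
    All randomness derives from ``config.seed`` via spawned child streams,
    one per subject, so cohorts are reproducible and subjects independent.
    """
    ss = np.random.SeedSequence(config.seed)
    if rng is not None:  # allow caller-provided entropy instead of config.seed
        ss = np.random.SeedSequence(rng.integers(0, 2**31))
    subjects: List[CohortSubject] = []
    counter = 0
    for arm, n_arm in zip(ARMS, config.n_per_arm):
        age_mu, age_sd = config.age_mean_sd[arm]
        base = config.pre_params[arm]
        mult = config.post_multipliers[arm]
        for _ in range(n_arm):
            counter += 1
            child = np.random.default_rng(ss.spawn(1)[0])
            age = float(child.normal(age_mu, age_sd))
            amp_l = float(np.exp(child.normal(0.0, config.subject_amp_sigma)))
            amp_h = float(np.exp(child.normal(0.0, config.subject_amp_sigma)))
            rr_m = float(np.exp(child.normal(0.0, config.subject_rr_sigma)))
            pre_params = replace(
                base,
                mean_rr=base.mean_rr * rr_m,
                lf_amp=base.lf_amp * amp_l,
                hf_amp=base.hf_amp * amp_h,
                seed=None,
            )
            post_params = replace(
                pre_params,
                mean_rr=pre_params.mean_rr * mult.get("mean_rr", 1.0),
                lf_amp=pre_params.lf_amp * mult.get("lf_amp", 1.0),
                hf_amp=pre_params.hf_amp * mult.get("hf_amp", 1.0),
            )
            pre = generate_rr_series(pre_params, rng=child)
            post = generate_rr_series(post_params, rng=child)
            subjects.append(
                CohortSubject(
                    subject_id=f"S{counter:03d}", arm=arm, age=age, pre=pre, post=post
                )
            )
    return subjects
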