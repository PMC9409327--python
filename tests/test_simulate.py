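"""Synthetic generator: determinism, spectral fidelity, ectopy injection, cohorts."""

import numpy as np
import pytest

from hrvkit.editing import edit_beats
from hrvkit.simulate import (
    CohortConfig,
    EctopyParams,
    RRGenParams,
    generate_cohort,
    generate_rr_series,
    inject_ectopy,
)


class TestGenerateRR:
    def test_constant_parameters_give_constant_series(self):
        p = RRGenParams(mean_rr=1000, lf_amp=0, hf_amp=0, noise_sd=0, duration=10)
        s = generate_rr_series(p)
        assert np.diff(s.times).tolist() == [1000] * 10
        assert (s.labels == "N").all()

    def test_sinusoid_bounded(self):
        p = RRGenParams(mean_rr=1000, lf_amp=50, lf_freq=0.1, hf_amp=0,
                        noise_sd=0, duration=1200)
        iv = np.diff(generate_rr_series(p).times)
        assert iv.min() >= 950 - 1 and iv.max() <= 1050 + 1  # 1 ms quantization slack

    def test_times_strictly_increasing_and_quantized(self):
        s = generate_rr_series(RRGenParams(seed=11))
        assert np.all(np.diff(s.times) > 0)
        assert s.times.dtype == np.int64

    def test_span_covers_duration(self):
        s = generate_rr_series(RRGenParams(duration=300, seed=2))
        assert s.duration_ms >= 300_000

    def test_seed_determinism(self):
        a = generate_rr_series(RRGenParams(seed=5))
        b = generate_rr_series(RRGenParams(seed=5))
        assert np.array_equal(a.times, b.times)

    def test_excessive_amplitude_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            generate_rr_series(RRGenParams(mean_rr=100, lf_amp=150, noise_sd=0, duration=60))

    def test_spectral_fidelity_total_variance(self):
        p = RRGenParams(mean_rr=1000, lf_amp=40, hf_amp=20, noise_sd=0,
                        duration=1200, seed=0)
        iv = np.diff(generate_rr_series(p).times).astype(float)
        assert np.var(iv) == pytest.approx((40**2 + 20**2) / 2, rel=0.05)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            RRGenParams(lf_freq=0.2)
        with pytest.raises(ValueError):
            RRGenParams(mean_rr=-1)
        with pytest.raises(ValueError):
            RRGenParams(hf_freq=0.5)


class TestInjectEctopy:
    def test_zero_fraction_is_identity(self):
        s = generate_rr_series(RRGenParams(duration=60, seed=1))
        out = inject_ectopy(s, EctopyParams(ectopic_fraction=0.0))
        assert np.array_equal(out.times, s.times)
        assert np.array_equal(out.labels, s.labels)

    def test_rounding_rule_count(self):
        s = generate_rr_series(RRGenParams(mean_rr=1000, lf_amp=0, hf_amp=0,
                                           noise_sd=0, duration=99))
        assert len(s) == 100
        out = inject_ectopy(s, EctopyParams(ectopic_fraction=0.03, seed=0))
        assert int(np.sum(out.labels != "N")) == 3

    def test_beat_count_and_order_preserved(self):
        s = generate_rr_series(RRGenParams(duration=600, seed=3))
        out = inject_ectopy(
            s, EctopyParams(ectopic_fraction=0.04, label_mix={"V": 0.5, "S": 0.5}, seed=4)
        )
        assert len(out) == len(s)
        assert np.all(np.diff(out.times) > 0)

    def test_v_beats_premature_s_beats_in_place(self):
        s = generate_rr_series(RRGenParams(mean_rr=1000, lf_amp=0, hf_amp=0,
                                           noise_sd=0, duration=99))
        out = inject_ectopy(
            s, EctopyParams(ectopic_fraction=0.03, label_mix={"V": 1.0, "S": 0.0},
                            prematurity=0.5, seed=0)
        )
        v_idx = np.flatnonzero(out.labels == "V")
        for i in v_idx:
            # advanced by half the local RR; successor held fixed (compensatory)
            assert out.times[i] == s.times[i] - 500
            assert out.times[i + 1] == s.times[i + 1]

    def test_editing_removes_injected_ectopy(self):
        # non-adjacent V beats: each removes its ending + succeeding interval
        s = generate_rr_series(RRGenParams(mean_rr=1000, lf_amp=0, hf_amp=0,
                                           noise_sd=0, duration=99))
        out = inject_ectopy(s, EctopyParams(ectopic_fraction=0.03, seed=0))
        v_idx = np.flatnonzero(out.labels == "V")
        if np.all(np.diff(v_idx) > 1):
            nn = edit_beats(out)
            assert len(nn) == (len(s) - 1) - 2 * len(v_idx)

    def test_determinism(self):
        s = generate_rr_series(RRGenParams(duration=300, seed=9))
        a = inject_ectopy(s, EctopyParams(ectopic_fraction=0.05, seed=7))
        b = inject_ectopy(s, EctopyParams(ectopic_fraction=0.05, seed=7))
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.labels, b.labels)


class TestCohort:
    def test_default_cohort_size(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        assert len(cohort) == 89
        arms = [s.arm for s in cohort]
        assert arms.count("land") == 30
        assert arms.count("water") == 29
        assert arms.count("control") == 30

    def test_seed_determinism(self):
        small = CohortConfig(n_per_arm=(2, 2, 2), seed=5)
        a = generate_cohort(small)
        b = generate_cohort(small)
        assert all(np.array_equal(x.pre.times, y.pre.times) for x, y in zip(a, b))
        assert [x.age for x in a] == [y.age for y in b]

    def test_null_multipliers_center_paired_differences_at_zero(self):
        cfg = CohortConfig(
            n_per_arm=(2, 12, 2),
            post_multipliers={
                arm: {"lf_amp": 1.0, "hf_amp": 1.0, "mean_rr": 1.0}
                for arm in ("land", "water", "control")
            },
            seed=3,
        )
        diffs = []
        for s in generate_cohort(cfg):
            if s.arm != "water":
                continue
            diffs.append(np.diff(s.post.times).mean() - np.diff(s.pre.times).mean())
        # no systematic pre/post shift: mean paired difference near zero
        assert abs(np.mean(diffs)) < 5.0

    def test_water_arm_younger_on_average(self):
        cohort = generate_cohort(CohortConfig(seed=1))
        ages = {}
        for arm in ("land", "water", "control"):
            ages[arm] = np.mean([s.age for s in cohort if s.arm == arm])
        assert ages["water"] < ages["land"]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_per_arm=(1, 5, 5))
        with pytest.raises(ValueError):
            CohortConfig(post_multipliers={"water": {"lf_amp": 0.0}})
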