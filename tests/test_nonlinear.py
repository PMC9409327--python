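"""Poincaré, sample entropy and DFA against closed forms and brute-force oracles."""

import numpy as np
import pytest

from hrvkit.nonlinear import dfa, poincare, sample_entropy

from conftest import make_nn


def sampen_brute(x, m, r):
    """Independent O(n^2) double-loop oracle returning the raw match counts."""
    x = np.asarray(x, float)
    nt = len(x) - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


class TestPoincare:
    def test_constant_series(self, constant_nn):
        sd1, sd2 = poincare(constant_nn)
        assert sd1 == pytest.approx(0.0, abs=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-9)

    def test_alternating_series_closed_form(self):
        # odd length -> balanced +-20 differences, mean difference exactly 0
        nn = make_nn([790.0, 810.0] * 100 + [790.0])
        sd1, sd2 = poincare(nn)
        assert sd1 == pytest.approx(np.sqrt(2) * 10, rel=1e-9)
        assert sd2 == pytest.approx(0.0, abs=1e-6)

    def test_sd1_rmssd_identity_for_zero_mean_differences(self, rng):
        # pin the last value to the first so the mean successive difference is 0
        vals = rng.uniform(700, 1100, 500)
        vals[-1] = vals[0]
        nn = make_nn(vals)
        sd1, _ = poincare(nn)
        d = np.diff(vals)
        rmssd = np.sqrt(np.mean(d**2))
        assert sd1 == pytest.approx(rmssd / np.sqrt(2), rel=1e-9)

    def test_sd_variance_identity(self, rng):
        vals = rng.uniform(700, 1100, 300)
        nn = make_nn(vals)
        sd1, sd2 = poincare(nn)
        x1, x2 = vals[:-1], vals[1:]
        pairwise_var = (np.var(x1) + np.var(x2)) / 2
        assert sd1**2 + sd2**2 == pytest.approx(2 * pairwise_var, rel=1e-9)

    def test_pairs_skip_gaps(self):
        contiguous = [False, True, False, True, True]
        nn = make_nn([800, 810, 2000, 2010, 2020], contiguous=contiguous)
        sd1, sd2 = poincare(nn)
        # pairs: (800,810), (2000,2010), (2010,2020); diffs all 10
        assert sd1 == pytest.approx(0.0, abs=1e-9)


class TestSampleEntropy:
    def test_constant_series_zero_entropy(self):
        assert sample_entropy(make_nn([1000.0] * 50), m=2, r=10.0) == 0.0

    def test_periodic_series_zero_entropy(self):
        # strict period-2 determinism: any m-match extends to m+1
        assert sample_entropy([790.0, 810.0] * 5, m=2, r=1.0) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        for n in (30, 80, 200):
            x = rng.uniform(0, 1, n)
            r = 0.2 * np.std(x)
            a, b = sampen_brute(x, 2, r)
            expected = -np.log(a / b) if a and b else None
            assert sample_entropy(x, m=2, r=r) == pytest.approx(expected, rel=1e-12)

    def test_no_matches_reported_missing(self, rng):
        x = np.arange(20, dtype=float) * 100
        assert sample_entropy(x, m=2, r=1.0) is None

    def test_iid_uniform_envelope(self, rng):
        # -ln P(extra point matches) for uniform with r = 0.2 sd is about 2.2
        vals = [sample_entropy(rng.uniform(0, 1, 1000), m=2, r=0.2 * np.sqrt(1 / 12))
                for _ in range(20)]
        assert np.mean(vals) == pytest.approx(2.2, abs=0.2)


class TestDFA:
    def test_brownian_profile_scaling(self):
        rng = np.random.default_rng(7)
        alphas = [dfa(np.cumsum(rng.normal(0, 10, 1200)))[0] for _ in range(20)]
        assert 1.4 <= np.mean(alphas) <= 1.6

    def test_fluctuation_matches_bruteforce_polyfit(self, rng):
        from hrvkit.nonlinear import dfa as dfa_impl

        x = rng.normal(1000, 30, 400)
        y = np.cumsum(x - x.mean())
        logn, logf = [], []
        for n in range(4, 12):
            nb = len(y) // n
            res2 = []
            for b in range(nb):
                seg = y[b * n:(b + 1) * n]
                t = np.arange(n)
                c = np.polyfit(t, seg, 1)
                res2.extend((seg - np.polyval(c, t)) ** 2)
            logn.append(np.log(n))
            logf.append(0.5 * np.log(np.mean(res2)))
        expected = np.polyfit(logn, logf, 1)[0]
        assert dfa_impl(x)[0] == pytest.approx(expected, rel=1e-9)

    def test_shift_invariance(self, rng):
        x = rng.normal(1000, 30, 500)
        a1, a2 = dfa(x)
        b1, b2 = dfa(x + 500.0)
        assert a1 == pytest.approx(b1, rel=1e-9)
        assert a2 == pytest.approx(b2, rel=1e-9)

    def test_monotone_trend_fluctuation_nondecreasing(self):
        x = np.linspace(800, 1200, 600)
        y = np.cumsum(x - x.mean())
        fs = []
        for n in (4, 8, 16, 32, 64):
            nb = len(y) // n
            segs = y[: nb * n].reshape(nb, n)
            t = np.arange(n, dtype=float)
            tc = t - t.mean()
            sl = segs @ tc / (tc**2).sum()
            resid = segs - segs.mean(1, keepdims=True) - sl[:, None] * tc
            fs.append(np.sqrt(np.mean(resid**2)))
        assert all(a <= b + 1e-12 for a, b in zip(fs, fs[1:]))

    def test_insufficient_length_missing(self):
        a1, a2 = dfa(np.random.default_rng(0).normal(1000, 30, 150))
        assert a1 is not None
        assert a2 is None
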