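import numpy as np
import pytest

from emgcancel.theory import (TheoryCase, empirical_crosscorr,
                              make_poisson_drive, verify_eq6, verify_eq7,
                              verify_eq10)

FS = 1000.0


def _biphasic(width=9):
    t = np.arange(width) - width // 2
    w = t * np.exp(-(t / 2.0) ** 2)
    return w / np.abs(w).max()


class TestCrossCorrelation:
    def test_zero_lag_matches_direct_sum(self, rng):
        x = rng.poisson(0.3, 500).astype(float)
        s = rng.poisson(0.2, 500).astype(float)
        r = empirical_crosscorr(x, s, max_lag=5)
        assert r[5] == pytest.approx((x * s).sum() / 500)

    def test_independence_limit(self, rng):
        x = rng.poisson(0.5, 200_000).astype(float)
        s = rng.poisson(0.5, 200_000).astype(float)
        r = empirical_crosscorr(x, s, max_lag=20)
        assert np.allclose(r, x.mean() * s.mean(), rtol=0.05)

    def test_delayed_copy_peaks_at_minus_delay(self):
        s = np.zeros(1000)
        s[100:900:50] = 1.0
        d = 7
        x = np.roll(s, d)  # x(t) = s(t - d)
        r = empirical_crosscorr(x, s, max_lag=20)
        assert np.argmax(r) - 20 == -d

    def test_max_lag_guard(self):
        with pytest.raises(ValueError):
            empirical_crosscorr(np.ones(10), np.ones(10), max_lag=10)


class TestCrossCorrelationIdentity:
    def test_delta_template_is_exact(self):
        s = make_poisson_drive(40, 20.0, FS, seed=0)
        rep = verify_eq6(TheoryCase(s, np.array([1.0]), FS), tol=1e-9)
        assert rep.passed

    def test_biphasic_template_converges(self):
        s = make_poisson_drive(30, 120.0, FS, seed=1)
        rep = verify_eq6(TheoryCase(s, _biphasic(), FS), tol=0.05)
        assert rep.passed
        assert rep.discrepancy < 0.05

    def test_zero_tolerance_fails_on_stochastic_input(self):
        s = make_poisson_drive(30, 10.0, FS, seed=2)
        rep = verify_eq6(TheoryCase(s, _biphasic(), FS), tol=0.0)
        assert not rep.passed


class TestCrossSpectrumIdentity:
    def test_delta_template_unity_ratio(self):
        s = make_poisson_drive(40, 60.0, FS, seed=3)
        rep = verify_eq7(TheoryCase(s, np.array([1.0]), FS))
        assert rep.passed
        ratio = rep.detail["ratio"]
        assert np.allclose(np.abs(ratio[2:-20]), 1.0, atol=0.2)

    def test_wide_template_tracks_rectified_spectrum(self):
        s = make_poisson_drive(40, 120.0, FS, seed=4)
        rep = verify_eq7(TheoryCase(s, _biphasic(15), FS))
        assert rep.passed
        # the rectified template acts as a low-pass: correlation with the
        # drive can never be perfect
        assert rep.detail["rho"] < 1.0

    def test_scale_invariance(self):
        s = make_poisson_drive(40, 60.0, FS, seed=5)
        r1 = verify_eq7(TheoryCase(s, _biphasic(), FS))
        r2 = verify_eq7(TheoryCase(s, 2.0 * _biphasic(), FS))
        assert r2.detail["rho"] == pytest.approx(r1.detail["rho"], abs=1e-12)
        sel = slice(5, 50)
        assert np.allclose(r2.detail["ratio"][sel], 2 * r1.detail["ratio"][sel],
                           rtol=1e-6)


class TestEstimatorOrdering:
    def test_nonnegative_template_gives_equality(self):
        s = make_poisson_drive(50, 30.0, FS, seed=6)
        rep = verify_eq10(TheoryCase(s, np.abs(_biphasic()), FS))
        assert rep.passed
        assert np.allclose(rep.detail["margin"], 0.0, atol=1e-12)

    def test_strict_inequality_with_overlap(self):
        # three overlapping discharges of a biphasic template
        s = np.zeros(2000)
        s[[500, 504, 509]] = 1.0
        rep = verify_eq10(TheoryCase(s, _biphasic(), FS))
        assert rep.passed
        mid = (rep.detail["margin"].size - 1) // 2
        assert rep.detail["margin"][mid] > 0

    def test_isolated_spike_equality(self):
        s = np.zeros(1000)
        s[400] = 1.0
        rep = verify_eq10(TheoryCase(s, _biphasic(), FS))
        assert rep.passed
        assert np.allclose(rep.detail["margin"], 0.0, atol=1e-12)

    def test_randomized_draws(self, rng):
        for k in range(5):
            width = int(rng.integers(3, 21))
            tmpl = rng.standard_normal(width)
            s = make_poisson_drive(float(rng.uniform(10, 80)), 30.0, FS,
                                   seed=100 + k)
            assert verify_eq10(TheoryCase(s, tmpl, FS)).passed

    def test_negative_drive_rejected(self):
        with pytest.raises(ValueError):
            TheoryCase(np.array([-1.0, 0.0]), np.ones(3), FS)
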