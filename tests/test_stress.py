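"""Relaxation-modulus estimator, tail/slope fits, and master-curve superposition."""

import numpy as np
import pytest

from dendrorelax.constants import KB_BAR_NM3
from dendrorelax.curves import RelaxationModulus
from dendrorelax.stress import (
    StressSeries,
    fit_loglog_slope,
    fit_tail_time,
    relaxation_modulus,
    superpose_master_curve,
    window_from_levels,
)


def make_series(components, volume=100.0, temperature=600.0, dt=1.0):
    return StressSeries(dt=dt, components=components, volume=volume, temperature=temperature)


class TestEstimator:
    def test_g0_equals_variance_combination(self, rng):
        sig = np.array([3.0, 1.0, 2.0, 0.5, 0.7, 0.9])
        comp = rng.standard_normal((4096, 6)) * sig
        s = make_series(comp)
        curve = relaxation_modulus(s)
        d = comp - comp.mean(axis=0)
        xx, yy, zz = d[:, 0], d[:, 1], d[:, 2]
        chans = [d[:, 3], d[:, 5], d[:, 4], xx - yy, yy - zz, zz - xx]
        wts = [6, 6, 6, 1, 1, 1]
        expected = s.volume / (30 * KB_BAR_NM3 * s.temperature) * sum(
            w * np.dot(c, c) / len(c) for w, c in zip(wts, chans)
        )
        assert curve.g0 == pytest.approx(expected, rel=1e-12)

    def test_axis_relabel_invariance(self, rng):
        comp = rng.standard_normal((2048, 6)) * np.array([2, 1, 3, 0.5, 0.8, 1.2])
        base = relaxation_modulus(make_series(comp))
        # swap x and y: xx<->yy, xz<->yz, xy unchanged
        swapped = comp[:, [1, 0, 2, 3, 5, 4]]
        alt = relaxation_modulus(make_series(swapped))
        assert np.allclose(alt.values, base.values, rtol=1e-12)

    def test_constant_offset_invariance(self, rng):
        comp = rng.standard_normal((2048, 6))
        base = relaxation_modulus(make_series(comp))
        shifted = relaxation_modulus(make_series(comp + 37.5))
        assert np.allclose(shifted.values, base.values, rtol=1e-10, atol=1e-12)

    def test_degenerate_constant_stress_flagged(self):
        comp = np.ones((512, 6)) * 5.0
        with pytest.warns(UserWarning, match="degenerate"):
            curve = relaxation_modulus(make_series(comp))
        assert np.allclose(curve.values, 0.0)
        assert "degenerate" in curve.provenance["flags"]

    def test_lag_truncation_warns(self, rng):
        comp = rng.standard_normal((256, 6))
        with pytest.warns(UserWarning, match="truncat"):
            curve = relaxation_modulus(make_series(comp), max_lag=1000)
        assert curve.times.max() <= 128.0


class TestSlopeFit:
    @pytest.mark.parametrize("exponent", [-0.7, 0.57, -0.45])
    def test_pure_power_law_recovered_exactly(self, exponent):
        t = np.geomspace(1, 1000, 60)
        slope, err = fit_loglog_slope(t, 5.0 * t**exponent, (1, 1000))
        assert slope == pytest.approx(exponent, abs=1e-12)
        assert err < 1e-12

    def test_rejects_nonpositive_values(self):
        t = np.geomspace(1, 100, 20)
        with pytest.raises(ValueError, match="positive"):
            fit_loglog_slope(t, np.linspace(1, -1, 20), (1, 100))

    def test_rejects_tiny_window(self):
        t = np.geomspace(1, 100, 20)
        with pytest.raises(ValueError, match="3 points"):
            fit_loglog_slope(t, t, (1, 1.1))


class TestTailFit:
    def test_pamam_value_recovered_to_four_figures(self):
        # exact curve exp(-2t/4.088 ns) on a quasi-log grid
        t = np.geomspace(100, 20000, 80)  # ps
        curve = RelaxationModulus(t, np.exp(-2 * t / 4088.0))
        fit = fit_tail_time(curve, (1000, 15000))
        assert fit.tau_max_ns == pytest.approx(4.088, rel=1e-4)
        assert fit.residual_rms < 1e-10

    @pytest.mark.parametrize("tau", [37.0, 512.0, 4088.0])
    def test_any_tau_exact(self, tau):
        t = np.geomspace(tau / 10, 3 * tau, 50)
        curve = RelaxationModulus(t, 2.5 * np.exp(-2 * t / tau))
        fit = fit_tail_time(curve, (t[0], t[-1]))
        assert fit.tau_max == pytest.approx(tau, rel=1e-10)

    def test_noisy_monte_carlo_recovery(self, rng):
        tau = 500.0
        t = np.geomspace(50, 1500, 40)
        recovered = []
        for _ in range(20):
            g = np.exp(-2 * t / tau) * (1 + 0.05 * rng.standard_normal(t.size))
            recovered.append(fit_tail_time(RelaxationModulus(t, g), (50, 1500)).tau_max)
        assert np.mean(recovered) == pytest.approx(tau, rel=0.05)

    def test_rejects_growing_curve(self):
        t = np.geomspace(1, 100, 30)
        with pytest.raises(ValueError, match="non-decaying"):
            fit_tail_time(RelaxationModulus(t, np.exp(t / 50)), (1, 100))

    def test_window_from_levels(self):
        t = np.geomspace(1, 5000, 200)
        curve = RelaxationModulus(t, 10 * np.exp(-2 * t / 1000.0))
        lo, hi = window_from_levels(curve, 0.01, 0.2)
        # normalized G in [0.01, 0.2] <=> t in [805, 2303]
        assert lo == pytest.approx(500 * np.log(5), rel=0.05)
        assert hi == pytest.approx(1000 * np.log(100) / 2, rel=0.05)


class TestSuperposition:
    def _curve(self, scale=1.0):
        t = np.geomspace(0.1, 100, 120) * scale
        return RelaxationModulus(t, np.exp(-t / (10 * scale)), normalized=True)

    def test_identity_for_equal_tau_rot(self):
        a, b = self._curve(), self._curve()
        m = superpose_master_curve([a, b], [5.0, 5.0])
        ref = np.interp(np.log(m.times), np.log(a.times), a.values)
        assert np.allclose(m.values, ref, rtol=1e-10)

    def test_self_similar_collapse(self):
        a = self._curve(1.0)
        b = self._curve(2.0)  # times x2, same shape; tau_rot x2
        m = superpose_master_curve([a, b], [1.0, 2.0])
        ref = np.interp(np.log(m.times), np.log(a.times), a.values)
        assert np.max(np.abs(m.values - ref)) < 1e-3  # grid-interpolation error only

    def test_gap_flagged_for_disjoint_curves(self):
        t1 = np.geomspace(0.1, 1, 20)
        t2 = np.geomspace(100, 1000, 20)
        a = RelaxationModulus(t1, np.exp(-t1), normalized=True)
        b = RelaxationModulus(t2, np.exp(-t2 / 500), normalized=True)
        with pytest.warns(UserWarning, match="gap"):
            m = superpose_master_curve([a, b], [1.0, 1.0])
        assert m.provenance["gaps"]

    def test_mixed_normalization_rejected(self):
        a = self._curve()
        t = np.geomspace(0.1, 100, 50)
        b = RelaxationModulus(t, 100 * np.exp(-t / 10))
        with pytest.raises(ValueError, match="normalized"):
            superpose_master_curve([a, b], [1.0, 1.0])

    def test_two_dt_gp_curves_merge_onto_target(self):
        # same Maxwell target sampled at dt differing x10: the merged master
        # curve must span the union window and match the target throughout
        from dendrorelax.stress import relaxation_modulus
        from dendrorelax.synthetic.gpstress import PronySeries, generate_stress_gp

        target = PronySeries(((40.0, 50.0),))
        fine = generate_stress_gp(target, dt=0.5, n_frames=1 << 17, volume=500.0,
                                  temperature=600.0, seed=21)
        coarse = generate_stress_gp(target, dt=5.0, n_frames=1 << 17, volume=500.0,
                                    temperature=600.0, seed=22)
        c1 = relaxation_modulus(fine).normalize()
        c2 = relaxation_modulus(coarse).normalize()
        m = superpose_master_curve([c1, c2], [1.0, 1.0])
        assert m.times.min() <= 1.0 and m.times.max() >= 1e4
        sel = (m.times > 0) & (m.values > 0.05)
        expected = target(m.times[sel]) / target.g0
        assert np.max(np.abs(m.values[sel] - expected)) < 0.05
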