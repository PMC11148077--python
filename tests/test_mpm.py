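"""MPM map estimation: ESTATICS, DAM B1, R1/A, MTsat, PD calibration."""

import numpy as np
import pytest
from scipy.optimize import brentq

from qmripls import mpm


def _train(contrast, tr, flip, te_ms, s0, r2s):
    te = np.asarray(te_ms, dtype=float)
    vols = s0[..., None] * np.exp(-r2s[..., None] * te / 1000.0)
    return mpm.EchoTrain(contrast, tr, flip, te, vols)


class TestEstatics:
    def test_two_point_exact(self):
        s0 = np.full((2, 2, 1), 100.0)
        r2s = np.full((2, 2, 1), 20.0)
        train = _train("PDw", 0.027, 6.0, [2.0, 12.0], s0, r2s)
        intercepts, fit = mpm.fit_estatics([train], np.ones_like(s0, bool))
        np.testing.assert_allclose(fit, 20.0, atol=1e-10)
        np.testing.assert_allclose(intercepts["PDw"], 100.0, rtol=1e-12)

    def test_zero_r2star_returns_constant_signal(self):
        s0 = np.full((2, 1, 1), 55.0)
        train = _train("T1w", 0.018, 20.0, [2.0, 8.0, 14.0], s0,
                       np.zeros_like(s0))
        intercepts, fit = mpm.fit_estatics([train], np.ones_like(s0, bool))
        np.testing.assert_allclose(fit, 0.0, atol=1e-10)
        np.testing.assert_allclose(intercepts["T1w"], 55.0, rtol=1e-12)

    def test_joint_three_contrast_recovery_matches_slope_oracle(self, rng):
        shape = (4, 4, 2)
        r2s = rng.uniform(10.0, 30.0, shape)
        s0s = {c: rng.uniform(50.0, 150.0, shape) for c in ("T1w", "PDw", "MTw")}
        trains = [
            _train("T1w", 0.018, 20.0, mpm.T1W_TE_MS, s0s["T1w"], r2s),
            _train("PDw", 0.027, 6.0, mpm.PDW_TE_MS, s0s["PDw"], r2s),
            _train("MTw", 0.027, 6.0, mpm.MTW_TE_MS, s0s["MTw"], r2s),
        ]
        intercepts, fit = mpm.fit_estatics(trains, np.ones(shape, bool))
        assert np.nanmax(np.abs(fit - r2s)) < 1e-6
        # independent oracle: per-contrast two-point log slope, averaged
        oracle = np.zeros(shape)
        for t in trains:
            te = t.te_ms / 1000.0
            oracle += (np.log(t.volumes[..., 0]) - np.log(t.volumes[..., -1])) \
                / (te[-1] - te[0])
        oracle /= len(trains)
        np.testing.assert_allclose(fit, oracle, atol=1e-8)

    def test_nonpositive_signal_flags_voxel(self):
        s0 = np.full((2, 1, 1), 100.0)
        train = _train("PDw", 0.027, 6.0, [2.0, 12.0], s0, np.full_like(s0, 20.0))
        train.volumes[0, 0, 0, 1] = -1.0
        intercepts, fit = mpm.fit_estatics([train], np.ones_like(s0, bool))
        assert np.isnan(fit[0, 0, 0]) and np.isfinite(fit[1, 0, 0])


class TestDam:
    def test_point_values(self):
        assert mpm.raw_dam_efficiency(100.0, 100.0, 60.0) == pytest.approx(1.0)
        assert mpm.raw_dam_efficiency(100.0, 0.0, 60.0) == pytest.approx(1.5)
        s2 = 2 * 100.0 * np.cos(np.deg2rad(66.0))
        assert mpm.raw_dam_efficiency(100.0, s2, 60.0) == pytest.approx(1.1)

    def test_polynomial_surface_recovers_smooth_field(self):
        shape = (10, 10, 6)
        ij = np.stack(np.meshgrid(*[np.linspace(-1, 1, n) for n in shape],
                                  indexing="ij"), axis=-1)
        f_true = 1.0 + 0.05 * ij[..., 0] - 0.03 * ij[..., 1] ** 2
        alpha = np.deg2rad(60.0)
        s_a = 500.0 * np.sin(f_true * alpha)
        s_2a = 500.0 * np.sin(2 * f_true * alpha)
        fmap = mpm.estimate_b1_dam(s_a, s_2a, 60.0, np.ones(shape, bool))
        assert np.abs(fmap.f - f_true).max() < 1e-6


class TestR1A:
    def test_exact_inverse_of_rational_model(self):
        r1, a = 1.0, 1000.0
        s_t1 = mpm.rational_flash_signal(a, r1, mpm.T1W_ACQ)
        s_pd = mpm.rational_flash_signal(a, r1, mpm.PDW_ACQ)
        r1_hat, a_hat = mpm.compute_r1_a(np.array(s_t1), np.array(s_pd))
        assert r1_hat == pytest.approx(1.0, abs=1e-12)
        assert a_hat == pytest.approx(1000.0, rel=1e-12)

    def test_b1_consistency(self):
        r1, a, f = 0.8, 500.0, 0.9
        s_t1 = mpm.rational_flash_signal(a, r1, mpm.T1W_ACQ, f=f)
        s_pd = mpm.rational_flash_signal(a, r1, mpm.PDW_ACQ, f=f)
        r1_hat, a_hat = mpm.compute_r1_a(np.array(s_t1), np.array(s_pd), f=f)
        assert r1_hat == pytest.approx(r1, abs=1e-12)
        assert a_hat == pytest.approx(a, rel=1e-12)

    def test_exact_flash_inputs_within_two_percent(self):
        r1_grid = np.linspace(0.5, 1.2, 15)
        s_t1 = mpm.exact_flash_signal(1000.0, r1_grid, mpm.T1W_ACQ)
        s_pd = mpm.exact_flash_signal(1000.0, r1_grid, mpm.PDW_ACQ)
        r1_hat, _ = mpm.compute_r1_a(s_t1, s_pd)
        assert np.max(np.abs(r1_hat - r1_grid) / r1_grid) < 0.02
        # independent oracle: exact-equation inversion by root finding
        def exact_r1(st1, spd):
            def g(r1):
                return (mpm.exact_flash_signal(1.0, r1, mpm.T1W_ACQ) / st1
                        - mpm.exact_flash_signal(1.0, r1, mpm.PDW_ACQ) / spd)
            return brentq(g, 0.05, 5.0)
        oracle = exact_r1(s_t1[7], s_pd[7])
        assert oracle == pytest.approx(r1_grid[7], rel=1e-9)

    def test_closed_form_agrees_with_direct_root_finding(self):
        # the closed form must match a numerical solve of the 2x2 rational system
        r1, a, f = 0.7, 300.0, 1.05
        s_t1 = mpm.rational_flash_signal(a, r1, mpm.T1W_ACQ, f=f)
        s_pd = mpm.rational_flash_signal(a, r1, mpm.PDW_ACQ, f=f)
        def g(r1x):
            return (s_t1 / mpm.rational_flash_signal(1.0, r1x, mpm.T1W_ACQ, f=f)
                    - s_pd / mpm.rational_flash_signal(1.0, r1x, mpm.PDW_ACQ, f=f))
        numeric = brentq(g, 0.05, 5.0)
        closed, _ = mpm.compute_r1_a(np.array(s_t1), np.array(s_pd), f=f)
        assert closed == pytest.approx(numeric, rel=1e-10)

    def test_nonphysical_pair_is_nan(self):
        r1_hat, a_hat = mpm.compute_r1_a(np.array(10.0), np.array(1.0))
        assert np.isnan(r1_hat) and np.isnan(a_hat)


class TestMtsat:
    def test_zero_saturation_is_exact(self):
        r1, a = 1.0, 1000.0
        s_mt = mpm.rational_flash_signal(a, r1, mpm.MTW_ACQ)
        delta = mpm.compute_mtsat(np.array(s_mt), np.array(a), np.array(r1))
        assert delta == pytest.approx(0.0, abs=1e-10)

    def test_b1_correction_identity_at_nominal_field(self):
        r1, a, true_delta = 1.0, 1000.0, 0.009
        alpha = mpm.MTW_ACQ.flip_rad
        s_mt = a * alpha * r1 * mpm.MTW_ACQ.tr / (
            r1 * mpm.MTW_ACQ.tr + alpha ** 2 / 2 + true_delta)
        raw = mpm.compute_mtsat(np.array(s_mt), np.array(a), np.array(r1),
                                f=1.0, corr_c=0.4)
        uncorr = mpm.compute_mtsat(np.array(s_mt), np.array(a), np.array(r1),
                                   f=1.0, corr_c=0.0)
        assert raw == pytest.approx(uncorr, rel=1e-12)
        assert raw == pytest.approx(true_delta * 100.0, rel=1e-10)


class TestPd:
    def test_linear_rescale_examples(self):
        a = np.array([1000.0, 1100.0])
        pd = mpm.calibrate_pd(a, np.ones(2, bool))
        np.testing.assert_allclose(pd, [65.714285, 72.285714], rtol=1e-6)
        const = mpm.calibrate_pd(np.full(5, 123.0), np.ones(5, bool))
        np.testing.assert_allclose(const, 69.0, rtol=1e-12)

    def test_ratios_preserved(self, rng):
        a = rng.uniform(100, 200, (4, 4))
        wm = np.zeros((4, 4), bool)
        wm[:2] = True
        pd = mpm.calibrate_pd(a, wm)
        np.testing.assert_allclose(pd / pd[0, 0], a / a[0, 0], rtol=1e-12)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            mpm.calibrate_pd(np.ones(3), np.zeros(3, bool))


def test_global_signal_scaling_leaves_quantitative_maps_unchanged(rng):
    shape = (3, 3, 2)
    r1 = rng.uniform(0.6, 1.0, shape)
    a = rng.uniform(500, 1500, shape)
    r2s = rng.uniform(12, 25, shape)

    def maps_for(scale):
        trains = []
        for contrast, acq, te in (("T1w", mpm.T1W_ACQ, mpm.T1W_TE_MS),
                                  ("PDw", mpm.PDW_ACQ, mpm.PDW_TE_MS),
                                  ("MTw", mpm.MTW_ACQ, mpm.MTW_TE_MS)):
            s0 = scale * mpm.rational_flash_signal(a, r1, acq)
            trains.append(_train(contrast, acq.tr, acq.flip_deg, te, s0, r2s))
        return mpm.fit_mpm(trains, np.ones(shape, bool))

    m1, m3 = maps_for(1.0), maps_for(3.0)
    np.testing.assert_allclose(m1.r1, m3.r1, rtol=1e-9)
    np.testing.assert_allclose(m1.r2star, m3.r2star, atol=1e-9)
    np.testing.assert_allclose(m1.mtsat, m3.mtsat, atol=1e-9)
    np.testing.assert_allclose(m3.a, 3.0 * m1.a, rtol=1e-9)
    np.testing.assert_allclose(m1.pd, m3.pd, rtol=1e-9)  # calibration removes gain


def test_small_angle_limit_of_exact_flash():
    acq = mpm.AcqParams(tr=0.018, flip_deg=1.0)
    exact = mpm.exact_flash_signal(1000.0, 1.0, acq)
    approx = mpm.rational_flash_signal(1000.0, 1.0, acq)
    assert abs(exact - approx) / exact < 1e-3
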