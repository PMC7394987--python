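"""Signal-to-concentration conversion, VIF extraction, dual-time merge."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bbbleak import (CalibrationCurve, ConcentrationSeries, DynamicSeries,
                     extract_vif, merge_dual_time, r1_to_concentration,
                     signal_to_r1, tissue_concentration)
from bbbleak.simulate import PhantomSpec, forward_patlak, simulate_subject


class TestSignalToR1:
    def test_baseline_signal_returns_r10(self):
        r10 = 1000.0 / 1100.0
        base = np.full(5, 40.0)
        r1, clamped = signal_to_r1(base, base, r10, td_ms=120.0)
        np.testing.assert_allclose(r1, r10, rtol=1e-12)
        assert not clamped.any()

    def test_linearized_regime_small_td_small_enhancement(self):
        # TD*R10 << 1: dR1 ~ (dS/S_base) * R10
        r10, td = 0.5, 1.0  # TD*R10 = 5e-4
        base = 10.0
        ds = 1e-4 * base
        r1, _ = signal_to_r1(base + ds, base, r10, td)
        assert r1 - r10 == pytest.approx((ds / base) * r10, rel=1e-3)

    def test_saturating_signal_is_clamped_and_flagged(self):
        r10 = 0.9
        # signal far above the saturation-recovery ceiling
        r1, clamped = signal_to_r1(np.array([1e4]), 1.0, r10, 120.0)
        assert clamped.all()
        assert np.isfinite(r1).all()

    @pytest.mark.parametrize("kwargs,msg", [
        (dict(td_ms=0.0), "td_ms"),
        (dict(td_ms=120.0, ceiling=1.5), "ceiling"),
    ])
    def test_invalid_arguments(self, kwargs, msg):
        with pytest.raises(ValueError, match=msg):
            signal_to_r1(np.ones(2), np.ones(2), 1.0, **kwargs)

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            signal_to_r1(np.ones(2), np.zeros(2), 1.0, 120.0)


class TestR1ToConcentration:
    def test_r10_gives_zero(self):
        assert r1_to_concentration(0.7, 0.7, 5.0) == 0.0

    def test_known_arithmetic(self):
        assert r1_to_concentration(1.2, 0.7, 5.0) == pytest.approx(0.1)

    def test_homogeneity_and_sign_preservation(self, rng):
        dr1 = rng.normal(0, 0.2, 100)
        c = r1_to_concentration(0.5 + dr1, 0.5, 4.2)
        np.testing.assert_allclose(
            r1_to_concentration(0.5 + 3 * dr1, 0.5, 4.2), 3 * c, rtol=1e-12)
        assert np.all(np.sign(c) == np.sign(dr1))


class TestCalibrationCurve:
    def make(self):
        return CalibrationCurve.from_saturation_recovery(1650.0, 120.0, 5.0)

    def test_monotone_inversion(self):
        cal = self.make()
        ratios = np.linspace(cal.ratios[0], cal.ratios[-1], 200)
        conc = cal.ratio_to_concentration(ratios)
        assert np.all(np.diff(conc) > 0)

    def test_out_of_range_refused_unless_extrapolate(self):
        cal = self.make()
        with pytest.raises(ValueError, match="outside calibration range"):
            cal.ratio_to_concentration(cal.ratios[-1] * 2)
        c = cal.ratio_to_concentration(cal.ratios[-1] * 2, extrapolate=True)
        assert np.isfinite(c)

    def test_non_monotone_table_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            CalibrationCurve(np.array([0.0, 1.0, 2.0]),
                             np.array([1.0, 3.0, 2.0]))

    def test_missing_zero_point_rejected(self):
        with pytest.raises(ValueError, match="zero-concentration"):
            CalibrationCurve(np.array([1.0, 2.0]), np.array([1.5, 2.0]))


class TestExtractVif:
    def test_all_baseline_series_gives_zero_cp(self, protocol):
        data = np.full((4, 4, 2, 10), 25.0)
        series = DynamicSeries(data, np.arange(10.0), "fast", 3)
        cal = CalibrationCurve.from_saturation_recovery(1650.0, 120.0, 5.0)
        vif = extract_vif(series, np.ones((4, 4, 2), bool), cal)
        np.testing.assert_allclose(vif.cp_mM, 0.0, atol=1e-12)

    def test_small_mask_rejected_naming_count(self, protocol):
        data = np.full((4, 4, 2, 10), 25.0)
        series = DynamicSeries(data, np.arange(10.0), "fast", 3)
        cal = CalibrationCurve.from_saturation_recovery(1650.0, 120.0, 5.0)
        mask = np.zeros((4, 4, 2), bool)
        mask.ravel()[:19] = True
        with pytest.raises(ValueError, match="19 < 20"):
            extract_vif(series, mask, cal)

    def test_noiseless_roundtrip_recovers_plasma_curve(self, noiseless_subject):
        s = noiseless_subject
        vif = extract_vif(s.fast, s.sinus_mask, s.calibration,
                          slow_series=s.slow, hematocrit=s.hematocrit)
        truth = np.interp(vif.times_s, s.truth.cp_times_s, s.truth.cp_mM)
        assert np.max(np.abs(vif.cp_mM - truth)) < 1e-9
        assert vif.times_s[-1] >= s.slow.times_s[-1]


class TestTissueConcentration:
    def test_noiseless_matches_forward_model(self, noiseless_subject,
                                             noiseless_products):
        s = noiseless_subject
        _, conc, _ = noiseless_products
        idx = np.searchsorted(s.truth.cp_times_s, conc.times_s)
        cp = s.truth.cp_mM[idx]
        vox = np.argwhere(s.masks.tertiary)[0]
        expect = forward_patlak(9.2e-7, 0.015, s.truth.cp_mM,
                                s.truth.cp_times_s)[idx]
        np.testing.assert_allclose(conc.data[tuple(vox)], expect, atol=1e-9)

    def test_precontrast_concentration_near_zero_under_noise(self):
        s = simulate_subject(PhantomSpec(noise_model="gaussian"), seed=21)
        conc = tissue_concentration(s.fast, s.slow, s.t10_ms,
                                    s.protocol.r1_relaxivity, s.brain_mask,
                                    s.protocol.td_ms)
        pre = conc.data[s.brain_mask][:, conc.times_s < s.truth.bolus_arrival_s]
        sigma = pre.std()
        assert abs(pre.mean()) < 3 * sigma / np.sqrt(pre.size)
        assert np.mean(np.abs(pre) < 3 * sigma) > 0.99

    def test_empty_mask_warns_and_returns_nan(self, noiseless_subject):
        s = noiseless_subject
        with pytest.warns(UserWarning, match="empty brain mask"):
            conc = tissue_concentration(
                s.fast, s.slow, s.t10_ms, s.protocol.r1_relaxivity,
                np.zeros(s.t10_ms.shape, bool), s.protocol.td_ms)
        assert np.isnan(conc.data).all()

    def test_grid_mismatch_rejected(self, noiseless_subject):
        s = noiseless_subject
        with pytest.raises(ValueError, match="grid mismatch"):
            tissue_concentration(s.fast, s.slow, s.t10_ms[:-1],
                                 s.protocol.r1_relaxivity,
                                 s.brain_mask[:-1], s.protocol.td_ms)


def _conc(times, role):
    data = np.zeros((2, 2, 1, len(times)))
    return ConcentrationSeries(data, np.asarray(times, float),
                               np.full(len(times), role))


class TestMergeDualTime:
    def test_fast_only_identity(self):
        fast = _conc([0.0, 1.0, 2.0], "fast")
        empty = ConcentrationSeries(np.zeros((2, 2, 1, 0)), np.zeros(0),
                                    np.zeros(0, dtype="<U4"))
        merged = merge_dual_time(fast, empty)
        np.testing.assert_array_equal(merged.times_s, fast.times_s)

    def test_dual_time_counts_and_monotonicity(self, noiseless_products):
        _, conc, _ = noiseless_products
        # 29 fast + 30 slow volumes merge into at most 59 ordered points
        assert conc.times_s.size <= 59
        assert np.all(np.diff(conc.times_s) > 0)
        assert set(conc.provenance) == {"fast", "slow"}

    def test_slow_points_inside_fast_window_are_dropped(self):
        fast = _conc([10.0, 20.0, 30.0], "fast")
        slow = _conc([5.0, 15.0, 40.0], "slow")
        merged = merge_dual_time(fast, slow)
        np.testing.assert_array_equal(merged.times_s,
                                      [5.0, 10.0, 20.0, 30.0, 40.0])

    def test_duplicate_slow_stamp_dropped_with_warning(self):
        fast = _conc([10.0, 20.0], "fast")
        slow = _conc([20.0, 40.0], "slow")
        with pytest.warns(UserWarning, match="coincide"):
            merged = merge_dual_time(fast, slow)
        np.testing.assert_array_equal(merged.times_s, [10.0, 20.0, 40.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0, 1000), min_size=1, max_size=20, unique=True),
           st.lists(st.floats(1001, 2000), min_size=1, max_size=20,
                    unique=True))
    def test_merge_always_strictly_increasing(self, tf, ts):
        fast = _conc(sorted(tf), "fast")
        slow = _conc(sorted(ts), "slow")
        merged = merge_dual_time(fast, slow)
        assert np.all(np.diff(merged.times_s) > 0)
        assert merged.provenance.size == merged.times_s.size
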