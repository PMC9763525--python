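"""Planar region values, time-activity fitting and absorbed-dose integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prrtdose.constants import JOULE_PER_KEV, LN2
from prrtdose.dosimetry import (
    PlanarSample,
    TimeActivityCurve,
    dose_rate_local,
    fit_organ_curve,
    fit_tumour_curve,
    planar_region_value,
    rescale_and_integrate,
    retime_spect,
)


def exp_samples(a0=100.0, t_eff=103.0, times=(1.0, 24.0, 96.0, 168.0)):
    lam = LN2 / t_eff
    return [PlanarSample(t, a0 * np.exp(-lam * t)) for t in times]


class TestPlanarRegionValue:
    def test_organ_mean_minus_thigh(self):
        assert planar_region_value(np.full((3, 3), 10.0), "organ", 4.0) == 6.0

    def test_tumour_five_highest(self):
        patch = np.array([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0]])
        assert planar_region_value(patch, "tumour") == pytest.approx(5.0)

    def test_organ_below_background_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            v = planar_region_value(np.full((2, 2), 3.0), "organ", 10.0)
        assert v == 0.0

    def test_small_tumour_patch_rejected(self):
        with pytest.raises(ValueError):
            planar_region_value(np.ones((2, 2)), "tumour")


class TestCurveFitting:
    def test_organ_tail_exact_on_exponential(self):
        curve = fit_organ_curve(exp_samples())
        assert curve.tail_A == pytest.approx(100.0, rel=1e-6)
        assert curve.t_eff_h == pytest.approx(103.0, rel=1e-6)
        assert curve.t_eff_h == pytest.approx(LN2 / curve.tail_lambda)

    def test_organ_early_segments_interpolate_samples(self):
        s = exp_samples()
        curve = fit_organ_curve(s)
        assert curve(s[0].time_h) == pytest.approx(s[0].signal)
        assert curve(0.0) == pytest.approx(0.0, abs=1e-12)
        mid = 0.5 * (s[0].time_h + s[1].time_h)
        expect = 0.5 * (s[0].signal + s[1].signal)
        assert curve(mid) == pytest.approx(expect)

    def test_non_decaying_tail_rejected(self):
        rising = [PlanarSample(t, s) for t, s in
                  [(1, 1.0), (24, 2.0), (96, 3.0), (168, 4.0)]]
        with pytest.raises(ValueError, match="non-decaying"):
            fit_organ_curve(rising)

    def test_noisy_tail_half_life_within_15pct_median(self):
        rng = np.random.default_rng(21)
        lam_true = LN2 / 103.0
        errs = []
        for _ in range(500):
            samples = [
                PlanarSample(t, 100 * np.exp(-lam_true * t) * rng.lognormal(0, 0.05))
                for t in (1.0, 24.0, 96.0, 168.0)
            ]
            errs.append(abs(fit_organ_curve(samples).tail_lambda / lam_true - 1))
        assert np.median(errs) < 0.15

    def test_tumour_tail_exact_and_slope_continuous(self):
        curve = fit_tumour_curve(exp_samples())
        assert curve.t_eff_h == pytest.approx(103.0, rel=1e-6)
        # C1 continuity with the tail at the switch time
        t2 = curve.t_switch
        h = 1e-5
        left = (curve(t2 - h) - curve(t2 - 2 * h)) / h
        right = -curve.tail_lambda * curve.tail_A * np.exp(-curve.tail_lambda * t2)
        assert left == pytest.approx(right, rel=1e-3)

    def test_tumour_curve_tracks_exponential_closely(self):
        lam = LN2 / 103.0
        curve = fit_tumour_curve(exp_samples())
        for t in (5.0, 12.0, 21.9, 23.0):
            assert curve(t) == pytest.approx(100 * np.exp(-lam * t), rel=0.01)

    def test_tumour_early_curve_non_negative(self):
        curve = fit_tumour_curve(exp_samples(t_eff=30.0))
        tt = np.linspace(0, curve.t_switch, 300)
        assert np.all(curve(tt) >= 0)

    def test_needs_four_increasing_samples(self):
        with pytest.raises(ValueError):
            fit_organ_curve(exp_samples(times=(1.0, 24.0, 96.0)))
        bad = exp_samples()
        bad[1] = PlanarSample(1.0, 5.0)
        with pytest.raises(ValueError, match="increasing"):
            fit_organ_curve(bad)


class TestDoseRate:
    def test_zero_and_linearity(self):
        assert dose_rate_local(0.0) == 0.0
        assert dose_rate_local(2e5) == pytest.approx(2 * dose_rate_local(1e5))

    def test_hand_unit_conversion(self):
        # 1e6 Bq/mL x 147.9 keV/decay in 1.04 g/mL tissue
        expected_gy_per_s = 1e6 * 147.9 * JOULE_PER_KEV * 1000.0 / 1.04
        assert dose_rate_local(1e6, 147.9, 1.04) == pytest.approx(
            expected_gy_per_s * 3600.0
        )


class TestRescaleAndIntegrate:
    def test_pure_exponential_closed_form(self):
        lam = LN2 / 103.0
        curve = TimeActivityCurve("organ", [], tail_A=1.0, tail_lambda=lam,
                                  t_switch=0.0)
        res = rescale_and_integrate(curve, dose_rate_at_spect_gy_per_h=0.05,
                                    t_spect_h=0.0)
        assert res.ad_per_ia_gy_per_gbq == pytest.approx(0.05 / lam, rel=1e-12)

    def test_known_piecewise_curve_hand_integral(self):
        # line 0->(2, 4) then flat-tail exponential attached at t=2
        lam = 0.1
        a = 4.0 / np.exp(-lam * 2.0)
        curve = TimeActivityCurve(
            "organ", [(0.0, 2.0, (0.0, 2.0))], tail_A=a, tail_lambda=lam,
            t_switch=2.0,
        )
        # scale = 1 when dose rate equals the curve value at t_spect
        res = rescale_and_integrate(curve, float(curve(2.0)), 2.0)
        hand = 0.5 * 2.0 * 4.0 + 4.0 / lam  # triangle + tail
        assert res.ad_per_ia_gy_per_gbq == pytest.approx(hand, rel=1e-12)

    @settings(derandomize=True, max_examples=40)
    @given(
        a0=st.floats(1.0, 1000.0),
        t_eff=st.floats(20.0, 150.0),
        bend=st.floats(0.5, 1.0),
    )
    def test_analytic_integral_matches_quadrature(self, a0, t_eff, bend):
        lam = LN2 / t_eff
        samples = [
            PlanarSample(t, a0 * np.exp(-lam * t) * (bend if i == 0 else 1.0))
            for i, t in enumerate((1.0, 24.0, 96.0, 168.0))
        ]
        for fitter in (fit_organ_curve, fit_tumour_curve):
            curve = fitter(samples)
            assert curve.integral() == pytest.approx(
                curve.integral_numeric(), rel=1e-6
            )

    def test_ad_invariant_to_planar_signal_scale(self):
        samples = exp_samples()
        scaled = [PlanarSample(s.time_h, 37.5 * s.signal) for s in samples]
        r1 = rescale_and_integrate(fit_tumour_curve(samples), 0.02, 21.9)
        r2 = rescale_and_integrate(fit_tumour_curve(scaled), 0.02, 21.9)
        assert r1.ad_per_ia_gy_per_gbq == pytest.approx(
            r2.ad_per_ia_gy_per_gbq, rel=1e-12
        )

    def test_zero_curve_value_at_spect_rejected(self):
        curve = TimeActivityCurve("organ", [(0.0, 2.0, (0.0, 1.0))],
                                  tail_A=1.0, tail_lambda=0.1, t_switch=2.0)
        with pytest.raises(ValueError):
            rescale_and_integrate(curve, 1.0, 0.0)


class TestRetime:
    def test_identity_and_doubling(self):
        assert retime_spect(5.0, 22.3, 22.3, 103.0) == 5.0
        assert retime_spect(5.0, 125.3, 22.3, 103.0) == pytest.approx(10.0)

    def test_off_schedule_hand_value(self):
        factor = 2.0 ** ((94.6 - 22.3) / 103.0)
        assert retime_spect(1.0, 94.6, 22.3, 103.0) == pytest.approx(factor)

    def test_bad_half_life_rejected(self):
        with pytest.raises(ValueError):
            retime_spect(1.0, 10.0, 5.0, 0.0)
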