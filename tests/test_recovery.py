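"""Recovery-coefficient models, volume map, organ RC and PSF estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from prrtdose.constants import (
    NEMA_SPHERE_VOLUMES_ML,
    PHANTOM_BACKGROUND_RATIOS,
    fwhm_to_sigma,
)
from prrtdose.phantoms import PhantomSpec, blur_and_noise, make_sphere_phantom, nema_phantom_spec
from prrtdose.recovery import (
    RCParams,
    SphereMeasurement,
    VolumeMapParams,
    apply_volume_map,
    estimate_psf_fwhm,
    fit_rc,
    fit_volume_map,
    organ_rc_from_mask,
    rc_full,
    rc_volume,
)

rc_params_st = st.builds(
    RCParams,
    alpha_ml=st.floats(0.5, 10.0),
    beta=st.floats(0.5, 3.0),
    f=st.floats(0.0, 1.0),
)


class TestRcVolume:
    def test_half_recovery_at_alpha(self):
        assert rc_volume(3.0, RCParams(3.0, 1.7, 0.5)) == pytest.approx(0.5)

    def test_large_volume_limit(self):
        assert rc_volume(1e9, RCParams(3.0, 1.5, 0.5)) == pytest.approx(1.0, abs=1e-6)

    def test_hand_evaluation(self):
        expected = 1.0 / (1.0 + (3.0 / 6.0) ** 1.5)
        assert rc_volume(6.0, RCParams(3.0, 1.5, 0.5)) == pytest.approx(expected)

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            rc_volume(0.0, RCParams(3.0, 1.5, 0.5))

    @settings(derandomize=True, max_examples=50)
    @given(params=rc_params_st)
    def test_strictly_increasing_in_volume(self, params):
        v = np.geomspace(0.1, 100.0, 50)
        r = rc_volume(v, params)
        assert np.all(np.diff(r) > 0)
        assert np.all((r > 0) & (r < 1))


class TestRcFull:
    @settings(derandomize=True, max_examples=100)
    @given(params=rc_params_st, vp=st.floats(0.1, 100.0))
    def test_boundary_identities(self, params, vp):
        assert rc_full(vp, 1.0, params) == pytest.approx(1.0, abs=1e-12)
        assert rc_full(vp, 0.0, params) == pytest.approx(
            rc_volume(vp, params), abs=1e-15
        )

    def test_linear_spill_in_when_f_is_one(self):
        params = RCParams(2.0, 1.2, 1.0)
        r0 = rc_volume(4.0, params)
        assert rc_full(4.0, 0.5, params) == pytest.approx(r0 + (1 - r0) * 0.5)

    def test_non_decreasing_in_eta(self):
        params = RCParams(2.0, 1.2, 0.3)
        eta = np.linspace(0, 1, 101)
        assert np.all(np.diff(rc_full(5.0, eta, params)) >= 0)

    def test_negative_eta_rejected(self):
        with pytest.raises(ValueError):
            rc_full(5.0, -0.1, RCParams(2.0, 1.2, 0.3))


def _grid_measurements(params, rng=None, noise_cv=0.0):
    out = []
    for v in NEMA_SPHERE_VOLUMES_ML:
        for eta in PHANTOM_BACKGROUND_RATIOS:
            r = rc_full(v, eta, params)
            if rng is not None and noise_cv > 0:
                r *= rng.lognormal(0.0, noise_cv)
            out.append(SphereMeasurement(v, eta, r * 1000.0, 1000.0))
    return out


class TestFitRc:
    def test_noiseless_self_consistency(self):
        true = RCParams(2.0, 1.2, 0.6)
        fit = fit_rc(_grid_measurements(true))
        assert fit.params.alpha_ml == pytest.approx(2.0, rel=1e-4)
        assert fit.params.beta == pytest.approx(1.2, rel=1e-4)
        assert fit.params.f == pytest.approx(0.6, rel=1e-4)
        assert not fit.degenerate_f

    def test_single_eta_flags_f_degeneracy(self):
        true = RCParams(2.0, 1.2, 0.6)
        meas = [m for m in _grid_measurements(true) if m.eta == 0.0]
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = fit_rc(meas)
        assert fit.degenerate_f
        assert fit.params.alpha_ml == pytest.approx(2.0, rel=1e-6)
        assert fit.params.beta == pytest.approx(1.2, rel=1e-6)

    def test_one_percent_noise_recovers_within_5pct(self):
        true = RCParams(2.0, 1.2, 0.6)
        rng = np.random.default_rng(11)
        fit = fit_rc(_grid_measurements(true, rng, 0.01))
        assert fit.params.alpha_ml == pytest.approx(2.0, rel=0.05)
        assert fit.params.beta == pytest.approx(1.2, rel=0.05)
        assert fit.params.f == pytest.approx(0.6, rel=0.05)

    def test_too_few_measurements_rejected(self):
        true = RCParams(2.0, 1.2, 0.6)
        with pytest.raises(ValueError):
            fit_rc(_grid_measurements(true)[:3])


class TestVolumeMap:
    TRUE = (0.5, 1.1, -0.8, 0.05)

    def _pairs(self):
        a0, a1, a2, a3 = self.TRUE
        out = []
        for vs in (0.5, 2.0, 8.0, 20.0):
            for eta in (0.0, 0.3, 0.6):
                out.append((vs, eta, a0 + a1 * vs + a2 * eta + a3 * vs * eta))
        return out

    def test_exact_recovery_on_noiseless_model_data(self):
        p = fit_volume_map(self._pairs())
        for got, want in zip((p.a0, p.a1, p.a2, p.a3), self.TRUE):
            assert got == pytest.approx(want, abs=1e-10)

    def test_identity_data_gives_identity_map(self):
        pairs = [(vs, eta, vs) for vs in (1.0, 5.0, 10.0) for eta in (0.0, 0.5)]
        p = fit_volume_map(pairs)
        assert p.a0 == pytest.approx(0.0, abs=1e-10)
        assert p.a1 == pytest.approx(1.0, abs=1e-10)
        assert p.a2 == pytest.approx(0.0, abs=1e-10)
        assert p.a3 == pytest.approx(0.0, abs=1e-10)

    def test_underdetermined_design_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            fit_volume_map([(1.0, 0.0, 1.0), (2.0, 0.0, 2.0), (3.0, 0.0, 3.0)])

    def test_apply_identity_and_hand_value(self):
        ident = VolumeMapParams(0.0, 1.0, 0.0, 0.0)
        assert apply_volume_map(7.3, 0.4, ident) == pytest.approx(7.3)
        p = VolumeMapParams(*self.TRUE)
        assert apply_volume_map(10.0, 0.25, p) == pytest.approx(11.425)

    def test_non_positive_result_floored_with_warning(self):
        p = VolumeMapParams(-5.0, 0.1, 0.0, 0.0)
        with pytest.warns(UserWarning, match="floor"):
            assert apply_volume_map(1.0, 0.0, p) == pytest.approx(0.1)


class TestOrganRc:
    def test_zero_fwhm_gives_unity(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[3:6, 3:6, 3:6] = True
        assert organ_rc_from_mask(mask, 0.0, 3.65) == 1.0

    def test_large_region_approaches_unity(self):
        mask = np.zeros((66, 66, 66), bool)
        mask[3:63, 3:63, 3:63] = True  # ~219 mm cube >> 6.4 mm FWHM
        assert organ_rc_from_mask(mask, 6.4, 3.65) > 0.95

    def test_matches_fine_grid_convolution_oracle(self):
        # 13 mL sphere at 3.65 mm voxels, FWHM 6.4 mm
        spec = PhantomSpec(sphere_volumes_ml=(13.0,), psf_fwhm_mm=6.4)
        _, mask = make_sphere_phantom(spec)
        region = mask.region(1)
        rc = organ_rc_from_mask(region, 6.4, 3.65)
        # oracle: same indicator upsampled 3x, convolved at fine resolution
        up = 3
        fine = np.repeat(np.repeat(np.repeat(region, up, 0), up, 1), up, 2)
        sigma = fwhm_to_sigma(6.4) / (3.65 / up)
        smeared = ndimage.gaussian_filter(fine.astype(float), sigma,
                                          mode="constant")
        rc_oracle = smeared[fine].mean()
        assert rc == pytest.approx(rc_oracle, rel=0.01)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            organ_rc_from_mask(np.zeros((5, 5, 5), bool), 6.4, 3.65)


class TestPsfEstimation:
    def test_self_consistency_at_6p4mm(self):
        truth, _ = make_sphere_phantom(nema_phantom_spec(0.0))
        measured = blur_and_noise(truth, 6.4)
        est = estimate_psf_fwhm(measured, truth, np.linspace(4.0, 9.0, 11))
        assert est == pytest.approx(6.4, abs=0.1)

    def test_noisy_recovery_within_0p3mm(self):
        truth, _ = make_sphere_phantom(nema_phantom_spec(0.0))
        measured = blur_and_noise(truth, 6.4, noise_scale=10000, seed=5)
        est = estimate_psf_fwhm(measured, truth, np.linspace(4.0, 9.0, 11))
        assert est == pytest.approx(6.4, abs=0.3)

    def test_boundary_minimum_raises(self):
        truth, _ = make_sphere_phantom(nema_phantom_spec(0.0))
        measured = blur_and_noise(truth, 6.4)
        with pytest.raises(ValueError, match="boundary"):
            estimate_psf_fwhm(measured, truth, np.linspace(8.0, 12.0, 5))
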