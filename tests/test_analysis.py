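import math

import numpy as np
import pytest

from afm_softscan import (
    AFMImage,
    ContactConfig,
    ForceCurve,
    HeightField,
    Material,
    TipGeometry,
    apparent_volume,
    build_force_volume,
    double_contact_force,
    fit_modulus,
    fourier_coefficients,
    fwhm,
    hertz_force,
    higher_order_content,
    isoforce_image,
    make_hemisphere,
    modulus_map,
    sneddon_modified_force,
    zero_force_topography,
)


class TestFWHM:
    def test_semicircle(self):
        r = 4.0
        x = np.linspace(-r, r, 4001)
        prof = np.sqrt(np.clip(r * r - x * x, 0, None))
        assert fwhm(prof, x=x) == pytest.approx(r * math.sqrt(3), rel=1e-4)

    def test_triangle(self):
        b = 6.0
        x = np.linspace(-b / 2, b / 2, 1201)
        prof = np.clip(1 - np.abs(x) / (b / 2), 0, None)
        assert fwhm(prof, x=x) == pytest.approx(b / 2, rel=1e-6)

    def test_dilated_hemisphere_matches_oracle(self, hemisphere5, tip_r1):
        xs = np.linspace(-7, 7, 281)
        img = zero_force_topography(tip_r1, hemisphere5, xs)
        got = fwhm(img.heights[:, 0], x=xs)
        # sphere-sphere dilation closed form: sqrt((r+R)^2 - x^2) - R = h/2
        # with peak h = r; solve for x
        peak = 5.0
        half = peak / 2.0
        x_half = math.sqrt((5 + 1) ** 2 - (half + 1) ** 2)
        assert got == pytest.approx(2 * x_half, rel=5e-3)

    def test_flat_profile_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            fwhm(np.zeros(10))

    def test_grid_refinement_second_order(self):
        r = 4.0
        errs = []
        for n in (101, 201, 401):
            x = np.linspace(-r, r, n)
            prof = np.sqrt(np.clip(r * r - x * x, 0, None))
            errs.append(abs(fwhm(prof, x=x) - r * math.sqrt(3)))
        assert errs[2] < errs[0]


class TestApparentVolume:
    def test_exact_hemisphere(self):
        hf = make_hemisphere(5.0, spacing=0.05)
        img = AFMImage(hf.x, hf.y, hf.heights, mode="zero-force")
        assert apparent_volume(img) == pytest.approx((2 / 3) * math.pi * 125, rel=5e-3)

    def test_dilation_volume_ratio(self):
        # R/r = 1.4 zero-force dilation: analytic sphere-sphere integral
        hemi = make_hemisphere(5.0, spacing=0.15, extent=11.0)
        tip = TipGeometry.from_degrees(7.0, 20.0)
        img = zero_force_topography(tip, hemi, hemi.x, hemi.y)
        v = apparent_volume(img)
        v_true = (2 / 3) * math.pi * 125
        v_oracle = 2 * math.pi * ((12**3 - 7**3) / 3 - 7 * (12**2 - 49) / 2)
        assert v / v_true == pytest.approx(v_oracle / v_true, rel=0.02)

    def test_monotone_in_setpoint(self, hemisphere5, tip_r1, material):
        d = np.concatenate([[0.0], np.geomspace(0.01, 0.65, 12)])
        vol = build_force_volume(tip_r1, hemisphere5, material,
                                 np.linspace(-6, 6, 41), delta_grid=d)
        vols = []
        for s in (0.02, 0.1, 0.23):
            img = isoforce_image(vol, s, dimensionless=True)
            img.heights = np.clip(img.heights, 0.0, None)
            vols.append(apparent_volume(img))
        assert vols[0] >= vols[1] >= vols[2]

    def test_empty_footprint_warns(self):
        img = AFMImage(np.arange(4.0), np.arange(3.0), np.zeros((4, 3)), mode="zero-force")
        with pytest.warns(UserWarning, match="baseline"):
            assert apparent_volume(img) == 0.0

    def test_half_max_footprint_smaller(self):
        hf = make_hemisphere(5.0, spacing=0.1)
        img = AFMImage(hf.x, hf.y, hf.heights, mode="zero-force")
        assert apparent_volume(img, "half-max") < apparent_volume(img)


class TestFourier:
    def test_pure_cosine(self):
        x = np.arange(200) / 200 * 10.0
        prof = 3.0 * np.cos(2 * np.pi * x / 10.0)
        spec = fourier_coefficients(prof, N=50, x=x)
        assert spec.A[1] == pytest.approx(3.0, abs=1e-12)
        assert np.abs(spec.A[2:]).max() < 1e-12

    def test_constant_profile(self):
        spec = fourier_coefficients(np.full(64, 2.5), N=10, period=8.0)
        assert spec.A[0] == pytest.approx(2.5)
        assert np.abs(spec.A[1:]).max() < 1e-12

    def test_square_wave_series(self):
        # symmetric square wave: A_n = (4A/pi)(-1)^((n-1)/2)/n for odd n
        M, A = 4000, 1.0
        x = np.arange(M) / M
        prof = np.where((x < 0.25) | (x >= 0.75), A, -A)
        spec = fourier_coefficients(prof, N=9, x=x)
        for n in (1, 3, 5, 7, 9):
            expected = (4 * A / math.pi) * (-1) ** ((n - 1) // 2) / n
            assert spec.A[n] == pytest.approx(expected, abs=2e-3)
        for n in (2, 4, 6, 8):
            assert abs(spec.A[n]) < 1e-12

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=8)
        lam = 5.0
        x = np.arange(256) / 256 * lam
        prof = sum(a * np.cos(2 * np.pi * n * x / lam) for n, a in enumerate(A))
        spec = fourier_coefficients(prof, N=7, x=x)
        np.testing.assert_allclose(spec.A, A, atol=1e-10)

    def test_parseval(self):
        rng = np.random.default_rng(4)
        A = rng.normal(size=6)
        lam = 3.0
        x = np.arange(512) / 512 * lam
        prof = sum(a * np.cos(2 * np.pi * n * x / lam) for n, a in enumerate(A))
        power_profile = np.mean(prof**2)
        power_coeffs = A[0] ** 2 + 0.5 * np.sum(A[1:] ** 2)
        assert power_profile == pytest.approx(power_coeffs, rel=1e-10)

    def test_nonuniform_sampling_raises(self):
        x = np.array([0.0, 0.1, 0.3, 0.35])
        with pytest.raises(ValueError, match="uniform"):
            fourier_coefficients(np.zeros(4), N=1, x=x)

    def test_reconstruct(self):
        x = np.arange(100) / 100 * 4.0
        prof = 1.0 + 0.5 * np.cos(2 * np.pi * x / 4.0)
        spec = fourier_coefficients(prof, N=5, x=x)
        np.testing.assert_allclose(spec.reconstruct(x), prof, atol=1e-10)


class TestHigherOrderContent:
    def test_pure_cosine_zero(self):
        x = np.arange(200) / 200 * 10.0
        spec = fourier_coefficients(np.cos(2 * np.pi * x / 10.0), N=50, x=x)
        assert higher_order_content(spec) < 1e-12

    def test_square_wave_dominated_by_a3(self):
        M = 2000
        x = np.arange(M) / M
        prof = np.where((x < 0.25) | (x >= 0.75), 1.0, -1.0)
        spec = fourier_coefficients(prof, N=50, x=x)
        assert higher_order_content(spec) > 0
        hi = np.abs(spec.A[2:51])
        assert np.argmax(hi) == 1  # A_3 dominates
        assert higher_order_content(spec, mode="rss") > higher_order_content(spec, mode="rms")


class TestFitModulus:
    def test_hertz_self_consistency(self, material):
        # generated with the true R*, fitted with the same radius
        d = np.linspace(0.0, 0.3, 30)[1:]
        F = hertz_force(material, ContactConfig(R=1.0), d)
        E, _ = fit_modulus(ForceCurve(delta=d, force=F), "hertz", R=1.0)
        assert E == pytest.approx(100.0, rel=1e-3)

    @pytest.mark.parametrize("model", ["hertz", "sneddon", "double_contact"])
    def test_family_self_consistency(self, material, model):
        d = np.linspace(0.0, 0.3, 25)[1:]
        tip = TipGeometry.from_degrees(1.0, 20.0)
        if model == "hertz":
            F = hertz_force(material, ContactConfig(R=1.0), d)
        elif model == "sneddon":
            F = sneddon_modified_force(material, tip, math.inf, d)
        else:
            F = double_contact_force(material, 1.0, 3.0, d)
        E, _ = fit_modulus(ForceCurve(delta=d, force=F), model, R=1.0, r=3.0,
                           theta=tip.theta)
        assert E == pytest.approx(100.0, rel=1e-3)

    def test_double_contact_data_hertz_underestimates(self, material):
        d = np.linspace(0.0, 0.3, 30)[1:]
        F = double_contact_force(material, 1.0, 3.0, d)
        curve = ForceCurve(delta=d, force=F)
        E_h, _ = fit_modulus(curve, "hertz", R=1.0)
        E_dc, _ = fit_modulus(curve, "double_contact", R=1.0, r=3.0)
        assert E_h < 100.0
        assert E_dc / 100.0 == pytest.approx(1.0, rel=1e-6)

    def test_force_ceiling_clips(self, material):
        d = np.linspace(0.0, 1.0, 40)[1:]
        F = hertz_force(material, ContactConfig(R=1.0), d)
        ceiling = float(F[20])
        E, _ = fit_modulus(ForceCurve(delta=d, force=F), "hertz", R=1.0,
                           force_ceiling_pn=ceiling)
        assert E == pytest.approx(100.0, rel=1e-3)
        with pytest.raises(ValueError, match="at least 5"):
            fit_modulus(ForceCurve(delta=d, force=F), "hertz", R=1.0,
                        force_ceiling_pn=float(F[2]))


class TestModulusMap:
    def test_flat_sample_constant_map(self, material, tip_r1):
        xg = np.linspace(-2, 2, 21)
        flat = HeightField(xg, xg, np.zeros((21, 21)),
                           principal_curvatures=lambda x, y: (0.0, 0.0))
        d = np.concatenate([[0.0], np.geomspace(0.005, 0.4, 15)])
        vol = build_force_volume(tip_r1, flat, material, np.linspace(-1, 1, 5),
                                 delta_grid=d)
        mm = modulus_map(vol, model="hertz", force_ceiling=0.1)
        assert not mm.failures
        np.testing.assert_allclose(mm.E_AFM, 100.0, rtol=1e-3)

    def test_hemisphere_centre_maximal(self, hemisphere5, material):
        tip = TipGeometry.from_degrees(1.0, 20.0)  # R/r = 0.2
        d = np.concatenate([[0.0], np.geomspace(0.013, 0.65, 12)])
        vol = build_force_volume(tip, hemisphere5, material,
                                 np.array([0.0, 1.25, 2.5, 3.75, 5.0]),
                                 delta_grid=d, engine="halfspace")
        mm = modulus_map(vol, model="hertz", force_ceiling=0.1)
        assert np.nanargmax(mm.E_AFM) == 0

    def test_sinusoid_trough_stiffer_than_crest(self, material):
        from afm_softscan import make_sinusoid

        sin = make_sinusoid(10.0, 10.0, spacing=0.1, y_extent=8.0)
        tip = TipGeometry.from_degrees(2.0, 20.0)  # R/lambda = 0.2
        d = np.concatenate([[0.0], np.geomspace(0.026, 1.3, 10)])
        vol = build_force_volume(tip, sin, material, np.array([0.0, 5.0]),
                                 delta_grid=d, engine="halfspace", window=5.0)
        mm = modulus_map(vol, model="hertz", force_ceiling=0.2)
        crest, trough = mm.E_AFM
        assert trough > crest
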