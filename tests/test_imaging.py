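"""Membrane-sheet image metrics: rel. SD, maxima, autocorrelation, fractions."""

import numpy as np
import pytest

import ionbridge as ib
from ionbridge.imaging import (ROI, AutocorrCurve, SheetImage,
                               expected_half_decay_radius, find_maxima)
from ionbridge.synthetic import ImageSpec, gen_sheet_image

from conftest import brute_force_maxima


def make_image(arr, px=65.0):
    return SheetImage(np.asarray(arr, dtype=float), px)


class TestBackgroundCorrectedMean:
    def test_constant_minus_background(self):
        img = make_image(np.full((20, 20), 10.0))
        img.pixels[:, 10:] = 4.0
        roi, bg = ROI(0, 0, 10, 20), ROI(10, 0, 10, 20)
        assert ib.background_corrected_mean(img, roi, bg) == pytest.approx(6.0)
        assert ib.background_corrected_mean(img, bg, bg) == pytest.approx(0.0)

    def test_recovers_generator_signal_level(self):
        spec = ImageSpec(width_px=64, height_px=64, background_level=30.0,
                         signal_per_px=50.0, clustered_fraction=0.0,
                         noise_model="gaussian", noise_sigma=2.0, seed=3)
        img, _ = gen_sheet_image(spec)
        # background known exactly; compare against a synthetic bg region
        full = np.hstack([img, np.full((64, 64), 30.0)])
        sim = make_image(full)
        got = ib.background_corrected_mean(sim, ROI(0, 0, 64, 64), ROI(64, 0, 64, 64))
        assert got == pytest.approx(50.0, abs=3 * 2.0 / 64)

    def test_empty_roi_rejected(self):
        img = make_image(np.ones((5, 5)))
        with pytest.raises(ValueError):
            ib.background_corrected_mean(img, ROI(0, 0, 0, 5), ROI(0, 0, 5, 5))


class TestRelativeSD:
    def test_uniform_roi_is_zero(self):
        img = make_image(np.full((10, 10), 7.0))
        assert ib.relative_sd(img, ROI(0, 0, 10, 10)) == 0.0

    def test_half_zeros_half_twos(self):
        arr = np.zeros((2, 10))
        arr[1] = 2.0
        assert ib.relative_sd(make_image(arr), ROI(0, 0, 10, 2)) == pytest.approx(1.0)

    def test_scale_invariance(self, spot_image, full_roi):
        img, spec, _ = spot_image
        roi = full_roi(img)
        base = ib.relative_sd(img, roi, background=spec.background_level)
        scaled = SheetImage(img.pixels * 3.7, img.pixel_size_nm)
        # background scales with the image under intensity multiplication
        assert ib.relative_sd(scaled, roi, background=3.7 * spec.background_level) \
            == pytest.approx(base, rel=1e-12)

    def test_additive_offset_decreases_uncorrected_cv(self, spot_image, full_roi):
        img, spec, _ = spot_image
        roi = full_roi(img)
        corrected = ib.relative_sd(img, roi, background=spec.background_level)
        uncorrected = ib.relative_sd(
            SheetImage(img.pixels + 50.0, img.pixel_size_nm), roi,
            background=spec.background_level)
        assert uncorrected < corrected

    def test_nonpositive_mean_rejected(self):
        img = make_image(np.full((5, 5), 2.0))
        with pytest.raises(ValueError, match="not positive"):
            ib.relative_sd(img, ROI(0, 0, 5, 5), background=2.0)

    def test_increases_with_clustered_fraction(self):
        means = {}
        for frac in (0.1, 0.5):
            vals = []
            for seed in range(20):
                spec = ImageSpec(width_px=64, height_px=64,
                                 clustered_fraction=frac, seed=seed)
                img, _ = gen_sheet_image(spec)
                si = SheetImage(img, spec.pixel_size_nm)
                vals.append(ib.relative_sd(si, ROI(0, 0, 64, 64),
                                           background=spec.background_level))
            means[frac] = np.mean(vals)
        assert means[0.5] > means[0.1]


class TestNormalizeToControl:
    def test_self_normalisation_and_doubling(self):
        control = [1.0, 2.0, 3.0]
        assert np.mean(ib.normalize_to_control(control, control)) == pytest.approx(1.0)
        np.testing.assert_allclose(ib.normalize_to_control([4.0], control), [2.0])

    def test_mixed_set_hand_computed(self):
        got = ib.normalize_to_control([3.0, 5.0], [2.0, 2.0, 5.0])
        np.testing.assert_allclose(got, [1.0, 5.0 / 3.0])

    def test_empty_control_rejected(self):
        with pytest.raises(ValueError):
            ib.normalize_to_control([1.0], [])


class TestFindMaxima:
    def test_flat_image_has_no_maxima(self):
        assert find_maxima(np.full((16, 16), 3.0), 1.0) == []

    def test_single_spot_located(self):
        spec = ImageSpec(width_px=48, height_px=48, cluster_density_per_um2=0.0,
                         clustered_fraction=0.0, seed=0)
        img, _ = gen_sheet_image(spec)
        yy, xx = np.mgrid[0:48, 0:48]
        img = img + 200.0 * np.exp(-((yy - 24.0) ** 2 + (xx - 20.0) ** 2) / 8.0)
        maxima = find_maxima(img, 10.0)
        assert len(maxima) == 1
        y, x = maxima[0]
        assert abs(y - 24) <= 1 and abs(x - 20) <= 1

    def test_count_non_increasing_in_noise_level(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 100, (32, 32))
        counts = [len(find_maxima(img, nl)) for nl in (1.0, 5.0, 20.0, 60.0)]
        assert counts == sorted(counts, reverse=True)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_prominence_search(self, seed):
        rng = np.random.default_rng(seed)
        img = np.round(rng.uniform(0, 30, (24, 24)))
        for nl in (2.0, 8.0):
            assert len(find_maxima(img, nl)) == len(brute_force_maxima(img, nl))

    def test_well_separated_spots_counted(self):
        img = np.zeros((64, 64))
        centers = [(10, 10), (10, 50), (40, 25), (55, 55)]
        yy, xx = np.mgrid[0:64, 0:64]
        for cy, cx in centers:
            img += 100.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / 6.0)
        maxima, density = ib.detect_clusters(make_image(img), ROI(0, 0, 64, 64), 20.0)
        assert len(maxima) == len(centers)
        area = 64 * 64 * (65 / 1000) ** 2
        assert density == pytest.approx(len(centers) / area)


class TestAutocorr:
    def test_zero_shift_is_unity(self, spot_image, full_roi):
        img, _, _ = spot_image
        curve = ib.autocorr_curve(img, full_roi(img), 10)
        assert curve.pcc[0] == 1.0

    def test_iid_noise_decorrelates(self):
        rng = np.random.default_rng(4)
        img = make_image(rng.normal(100, 10, (80, 80)))
        curve = ib.autocorr_curve(img, ROI(0, 0, 80, 80), 5)
        n = 80 * 75
        assert np.all(np.abs(curve.pcc[1:]) < 3 / np.sqrt(n))

    def test_pcc_scale_invariant(self, spot_image, full_roi):
        img, _, _ = spot_image
        roi = full_roi(img)
        c1 = ib.autocorr_curve(img, roi, 8)
        c2 = ib.autocorr_curve(SheetImage(img.pixels * 5.0, img.pixel_size_nm), roi, 8)
        np.testing.assert_allclose(c1.pcc, c2.pcc, atol=1e-12)

    def test_gaussian_spot_curve_matches_closed_form(self):
        # dense non-overlapping spot field: PCC(d) ~ exp(-d^2/(4 sigma^2))
        sigma = 2.0
        rng = np.random.default_rng(9)
        img = np.zeros((256, 256))
        yy, xx = np.mgrid[0:256, 0:256]
        for _ in range(120):
            cy, cx = rng.uniform(10, 246, 2)
            img += np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma ** 2))
        curve = ib.autocorr_curve(make_image(img, px=1.0), ROI(0, 0, 256, 256), 6)
        expected = np.exp(-curve.shifts_px ** 2 / (4 * sigma ** 2))
        # spot overlap adds a small baseline; compare above it
        assert np.allclose(curve.pcc[:5], expected[:5], atol=0.08)

    def test_average_curves(self):
        c1 = AutocorrCurve(np.arange(3), np.array([1.0, 0.5, 0.2]), 65.0)
        c2 = AutocorrCurve(np.arange(3), np.array([1.0, 0.3, 0.0]), 65.0)
        avg = ib.average_curves([c1, c2])
        np.testing.assert_allclose(avg.pcc, [1.0, 0.4, 0.1])
        np.testing.assert_allclose(ib.average_curves([c1]).pcc, c1.pcc)

    def test_average_excludes_missing_pointwise(self):
        c1 = AutocorrCurve(np.arange(3), np.array([1.0, np.nan, 0.2]), 65.0)
        c2 = AutocorrCurve(np.arange(3), np.array([1.0, 0.3, 0.0]), 65.0)
        np.testing.assert_allclose(ib.average_curves([c1, c2]).pcc, [1.0, 0.3, 0.1])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ib.average_curves([])


class TestRadiusFromAutocorr:
    def test_exact_gaussian_curve_half_decay(self):
        sigma = 2.0
        shifts = np.arange(0, 13)
        curve = AutocorrCurve(shifts, np.exp(-shifts ** 2 / (4 * sigma ** 2)), 1.0)
        true = 2 * sigma * np.sqrt(np.log(2))
        assert ib.radius_from_autocorr(curve, 4) == pytest.approx(true, rel=0.05)

    def test_linear_curve_half_decay_is_midpoint(self):
        shifts = np.arange(0, 11)
        curve = AutocorrCurve(shifts, 1.0 - shifts / 10.0, 1.0)
        assert ib.radius_from_autocorr(curve, 1) == pytest.approx(5.0, rel=1e-6)

    def test_radius_scales_with_pixel_size(self):
        shifts = np.arange(0, 11)
        pcc = 1.0 - shifts / 10.0
        r1 = ib.radius_from_autocorr(AutocorrCurve(shifts, pcc, 65.0), 1)
        r2 = ib.radius_from_autocorr(AutocorrCurve(shifts, pcc, 130.0), 1)
        assert r2 == pytest.approx(2 * r1)

    def test_non_decaying_curve_rejected(self):
        shifts = np.arange(0, 11)
        curve = AutocorrCurve(shifts, np.full(11, 1.0), 1.0)
        with pytest.raises(ValueError, match="decay"):
            ib.radius_from_autocorr(curve, 2)

    def test_spot_field_radius_recovery(self):
        # 20 seeds; recovered radius vs closed-form half-decay of the
        # generator's Gaussian profile (2 sqrt(ln2) sigma)
        radius = 80.0
        target = expected_half_decay_radius(radius)
        got = []
        for seed in range(20):
            spec = ImageSpec(width_px=128, height_px=128, pixel_size_nm=65.0,
                             cluster_radius_nm=radius, clustered_fraction=0.5,
                             cluster_density_per_um2=1.0, seed=seed)
            img, _ = gen_sheet_image(spec)
            si = SheetImage(img, spec.pixel_size_nm)
            curve = ib.autocorr_curve(si, ROI(0, 0, 128, 128), 8)
            got.append(ib.radius_from_autocorr(curve, 4))
        assert np.mean(got) == pytest.approx(target, rel=0.20)


class TestClusteredFraction:
    def test_uniform_image_is_zero(self):
        img = make_image(np.full((20, 20), 5.0))
        with np.errstate(all="ignore"):
            assert ib.clustered_fraction(img, ROI(0, 0, 20, 20)) == 0.0

    def test_single_bright_pixel_dominates(self):
        arr = np.zeros((20, 20))
        arr[3, 3] = 1000.0
        arr += 0.001  # keep total positive everywhere
        frac = ib.clustered_fraction(make_image(arr), ROI(0, 0, 20, 20))
        assert frac > 0.99

    def test_monotone_in_generated_fraction(self):
        measured = []
        for f in (0.1, 0.3, 0.5, 0.7, 0.9):
            vals = []
            for seed in range(8):
                spec = ImageSpec(width_px=64, height_px=64, clustered_fraction=f,
                                 seed=100 + seed)
                img, _ = gen_sheet_image(spec)
                si = SheetImage(img, spec.pixel_size_nm)
                vals.append(ib.clustered_fraction(si, ROI(0, 0, 64, 64),
                                                  background=spec.background_level))
            measured.append(np.mean(vals))
        assert measured == sorted(measured)
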