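"""Key measures: centroid, diameters, radius profiles, ratios and errors."""

import numpy as np
import pytest

from conftest import rasterized_circle
from fundusseg.measures import (
    average_radius_ratio_errors,
    centroid,
    key_measures,
    measure_errors,
    radius_profile,
    radius_ratio_errors,
    rim_profile,
    vertical_diameter,
)


def rasterized_ellipse(a, b, size=256, center=(128, 128)):
    rr, cc = np.mgrid[0:size, 0:size]
    return ((rr - center[0]) / a) ** 2 + ((cc - center[1]) / b) ** 2 <= 1.0


class TestCentroid:
    def test_single_pixel(self):
        mask = np.zeros((32, 32), bool)
        mask[20, 10] = True  # row 20, col 10 -> (x, y) = (10, 20)
        assert centroid(mask) == (10.0, 20.0)

    def test_centered_circle(self):
        xc, yc = centroid(rasterized_circle(50))
        assert abs(xc - 128) <= 0.5 and abs(yc - 128) <= 0.5

    def test_blob_equals_brute_force_mean(self):
        rng = np.random.default_rng(0)
        mask = rng.random((40, 40)) > 0.6
        xs, ys = [], []
        for r in range(40):
            for c in range(40):
                if mask[r, c]:
                    xs.append(c)
                    ys.append(r)
        assert centroid(mask) == (np.mean(xs), np.mean(ys))

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            centroid(np.zeros((8, 8), bool))


class TestVerticalDiameter:
    def test_single_row(self):
        mask = np.zeros((10, 10), bool)
        mask[4, 2:8] = True
        assert vertical_diameter(mask) == 1

    def test_circle_radius_50_spans_101_rows(self):
        assert vertical_diameter(rasterized_circle(50)) == 101

    def test_tall_ellipse_spans_161_rows(self):
        assert vertical_diameter(rasterized_ellipse(80, 40)) == 161


class TestRadiusProfile:
    def test_default_profile_has_360_samples(self):
        prof = radius_profile(rasterized_circle(40))
        assert len(prof) == 360
        assert np.array_equal(prof.angles, np.arange(360))

    def test_circle_radius_100_all_radii_near_100(self):
        prof = radius_profile(rasterized_circle(100), center=(128.0, 128.0))
        assert np.all(prof.radii >= 99) and np.all(prof.radii <= 101)

    def test_square_corner_radius_is_sqrt2_times_side(self):
        mask = np.zeros((201, 201), bool)
        mask[50:151, 50:151] = True  # half-side 50, centred at (100, 100)
        prof = radius_profile(mask, center=(100.0, 100.0))
        assert abs(prof.radii[0] - 50) <= 1
        assert abs(prof.radii[45] - 50 * np.sqrt(2)) <= 1

    def test_no_gaps_for_convex_mask(self):
        prof = radius_profile(rasterized_circle(30))
        assert np.all(prof.radii > 0)
        assert len(prof.radii) == 360

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            radius_profile(np.zeros((8, 8), bool))


class TestRimProfile:
    def test_cup_equal_disc_gives_zero_rim(self):
        prof = radius_profile(rasterized_circle(50), center=(128.0, 128.0))
        rim = rim_profile(prof, prof)
        assert np.all(rim.radii == 0)

    def test_concentric_circles_rim_thickness(self):
        c = (128.0, 128.0)
        disc = radius_profile(rasterized_circle(100), center=c)
        cup = radius_profile(rasterized_circle(50), center=c)
        rim = rim_profile(disc, cup)
        assert np.all(np.abs(rim.radii - 50) <= 2)

    def test_cup_outside_disc_clamped_with_flag(self):
        c = (128.0, 128.0)
        disc = radius_profile(rasterized_circle(60), center=c)
        cup = radius_profile(rasterized_circle(50), center=c)
        cup.radii[90] = 75.0  # force a protruding cup radius at one angle
        rim = rim_profile(disc, cup)
        assert rim.radii[90] == 0 and rim.clamped[90]
        assert not rim.clamped[0]

    def test_mismatched_centres_rejected(self):
        disc = radius_profile(rasterized_circle(60), center=(128.0, 128.0))
        cup = radius_profile(rasterized_circle(30), center=(120.0, 128.0))
        with pytest.raises(ValueError):
            rim_profile(disc, cup)


class TestKeyMeasures:
    def test_cup_equal_disc(self):
        disc = rasterized_circle(40)
        km = key_measures(disc, disc)
        assert (km.cdr, km.cdar, km.rdar) == (1.0, 1.0, 0.0)

    def test_concentric_circles_ratios(self):
        km = key_measures(rasterized_circle(100), rasterized_circle(50))
        assert km.cdr == pytest.approx(101 / 201)
        assert km.cdar == pytest.approx(0.25, abs=0.01)

    def test_area_ratios_sum_to_one_for_contained_cup(self):
        km = key_measures(rasterized_circle(80), rasterized_circle(35))
        assert km.cdar + km.rdar == 1.0

    def test_empty_cup_degenerate_case(self):
        km = key_measures(rasterized_circle(40), np.zeros((256, 256), bool))
        assert (km.cdr, km.cdar, km.rdar) == (0.0, 0.0, 1.0)

    def test_empty_disc_raises(self):
        with pytest.raises(ValueError):
            key_measures(np.zeros((8, 8), bool), np.zeros((8, 8), bool))


class TestMeasureErrors:
    def test_identical_measures_zero_errors(self):
        km = key_measures(rasterized_circle(60), rasterized_circle(30))
        err = measure_errors(km, km)
        assert (err.cdre, err.cdare, err.rdare) == (0.0, 0.0, 0.0)

    def test_absolute_difference(self):
        a = key_measures(rasterized_circle(100), rasterized_circle(50))
        b = key_measures(rasterized_circle(100), rasterized_circle(60))
        err = measure_errors(a, b)
        assert err.cdre == pytest.approx(abs(a.cdr - b.cdr))

    def test_area_errors_coincide_when_cup_contained(self):
        # CDAR + RDAR = 1 on both sides forces CDARE == RDARE
        a = key_measures(rasterized_circle(100), rasterized_circle(50))
        b = key_measures(rasterized_circle(100), rasterized_circle(62))
        err = measure_errors(a, b)
        assert err.cdare == pytest.approx(err.rdare, abs=1e-12)


class TestRadiusRatioErrors:
    def test_identical_profiles_all_zero(self):
        prof = radius_profile(rasterized_circle(70))
        errs, n_excl = radius_ratio_errors(prof, prof)
        assert n_excl == 0 and np.all(errs == 0)

    def test_constant_offset_gives_constant_ratio(self):
        c = (128.0, 128.0)
        gt = radius_profile(rasterized_circle(100), center=c)
        est = radius_profile(rasterized_circle(100), center=c)
        est.radii = gt.radii * 0.9
        errs, _ = radius_ratio_errors(gt, est)
        assert np.allclose(errs, 0.1)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(5)
        c = (128.0, 128.0)
        gt = radius_profile(rasterized_circle(60), center=c)
        est = radius_profile(rasterized_circle(60), center=c)
        est.radii = gt.radii + rng.normal(0, 3, 360)
        errs, _ = radius_ratio_errors(gt, est)
        for m in range(360):
            expected = abs(gt.radii[m] - est.radii[m]) / gt.radii[m]
            assert errs[m] == pytest.approx(expected, abs=1e-12)

    def test_zero_gt_angles_excluded(self):
        c = (128.0, 128.0)
        gt = radius_profile(rasterized_circle(60), center=c)
        est = radius_profile(rasterized_circle(60), center=c)
        gt.radii[10] = 0.0
        errs, n_excl = radius_ratio_errors(gt, est)
        assert n_excl == 1 and np.isnan(errs[10])

    def test_averaging_matches_sum_over_count(self):
        rng = np.random.default_rng(6)
        series = rng.random(360)
        series[[3, 77]] = np.nan
        valid = series[~np.isnan(series)]
        expected = valid.sum() / valid.size
        assert average_radius_ratio_errors(series) == pytest.approx(expected, abs=1e-12)

    def test_constant_series_average(self):
        assert average_radius_ratio_errors(np.full(360, 0.1)) == pytest.approx(0.1)

    def test_uniform_radial_scaling_recovers_scale_factor(self):
        # rasterize r=100 and r=110 circles: ADRRE should be 0.10 +- pixelization
        c = (128.0, 128.0)
        gt = radius_profile(rasterized_circle(100), center=c)
        est = radius_profile(rasterized_circle(110), center=c)
        errs, _ = radius_ratio_errors(gt, est)
        assert average_radius_ratio_errors(errs) == pytest.approx(0.10, abs=0.02)
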