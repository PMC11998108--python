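"""Needle shape profiles, revolved volumes and depth-band scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnswell.exceptions import RangeError, ValidationError
from mnswell.geometry import (
    DEFAULT_BAND,
    DEFAULT_SHAPES,
    DEFAULT_SWELL,
    DepthBand,
    RadialProfile,
    ShapeParams,
    SwellIncrement,
    apply_swell,
    band_volume,
    band_volume_fraction,
    fit_profile_curve,
    percent_volume_change,
    revolve_volume,
    shape_profile,
)


class TestShapeProfile:
    def test_conical_is_linear_taper(self):
        p = shape_profile(ShapeParams("conical", 900.0, 150.0), n_samples=901)
        assert p.r[0] == 0.0
        assert p.r[-1] == pytest.approx(150.0)
        np.testing.assert_allclose(p.r, 150.0 * p.x / 900.0, rtol=1e-12)

    def test_candlelit_max_radius_at_head_center(self):
        params = ShapeParams("candlelit", height=900.0, base_radius=100.0,
                             head_radius=177.0, head_center=250.0, shaft_radius=100.0)
        p = shape_profile(params, n_samples=9001)
        assert np.max(p.r) == pytest.approx(177.0, abs=1e-3)
        assert p.x[np.argmax(p.r)] == pytest.approx(250.0, abs=0.5)
        # tip is sharp, shaft is cylindrical
        assert p.r[0] == 0.0
        assert p.r[-1] == pytest.approx(100.0)

    def test_candlelit_is_continuous(self):
        p = shape_profile(DEFAULT_SHAPES["candlelit"], n_samples=20001)
        assert np.max(np.abs(np.diff(p.r))) < 1.0  # no jumps at piece joints

    def test_funnel_monotone_flare(self):
        p = shape_profile(DEFAULT_SHAPES["funnel"], n_samples=901)
        assert np.all(np.diff(p.r) >= 0)
        assert p.r[-1] == pytest.approx(150.0)
        # convex flare: second half gains more radius than the first
        mid = len(p.r) // 2
        assert p.r[-1] - p.r[mid] > p.r[mid] - p.r[0]

    @pytest.mark.parametrize("bad", [
        dict(family="pyramid", height=900.0, base_radius=150.0),
        dict(family="conical", height=-1.0, base_radius=150.0),
        dict(family="conical", height=900.0, base_radius=0.0),
        dict(family="candlelit", height=900.0, base_radius=100.0,
             head_radius=177.0, head_center=950.0, shaft_radius=100.0),
        dict(family="candlelit", height=900.0, base_radius=100.0,
             head_radius=90.0, head_center=250.0, shaft_radius=100.0),
        dict(family="funnel", height=900.0, base_radius=150.0, shaft_radius=200.0),
    ])
    def test_nonphysical_parameters_rejected(self, bad):
        with pytest.raises(ValidationError):
            ShapeParams(**bad)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValidationError):
            RadialProfile(x=np.array([10.0, 20.0]), r=np.array([1.0, 2.0]))  # tip not at 0
        with pytest.raises(ValidationError):
            RadialProfile(x=np.array([0.0, 5.0, 5.0]), r=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValidationError):
            RadialProfile(x=np.array([0.0, 5.0]), r=np.array([1.0, -2.0]))


class TestRevolveVolume:
    @pytest.mark.parametrize("profile_builder,closed_form", [
        (lambda: shape_profile(ShapeParams("conical", 900.0, 150.0), 1001),
         math.pi * 150.0**2 * 900.0 / 3.0),
        (lambda: RadialProfile(np.array([0.0, 500.0]), np.array([100.0, 100.0])),
         math.pi * 100.0**2 * 500.0),
        (lambda: RadialProfile(np.linspace(0, 200, 2001),
                               np.sqrt(np.maximum(200.0**2 - np.linspace(0, 200, 2001)**2, 0))),
         2.0 * math.pi * 200.0**3 / 3.0),
    ], ids=["cone", "cylinder", "hemisphere"])
    def test_matches_closed_forms(self, profile_builder, closed_form):
        assert revolve_volume(profile_builder()) == pytest.approx(closed_form, rel=5e-3)

    def test_error_halves_under_sample_doubling(self):
        R = 200.0
        exact = 2.0 * math.pi * R**3 / 3.0
        errs = []
        for n in (251, 501, 1001, 2001):
            x = np.linspace(0.0, R, n)
            hemi = RadialProfile(x, np.sqrt(np.maximum(R * R - x * x, 0.0)))
            errs.append(abs(revolve_volume(hemi) - exact) / exact)
        assert all(later <= 0.5 * earlier for earlier, later in zip(errs, errs[1:]))

    def test_additive_over_split_intervals(self, default_profiles):
        for p in default_profiles.values():
            total = revolve_volume(p, 0.0, p.height)
            split = 337.19  # deliberately off any sample point
            parts = revolve_volume(p, 0.0, split) + revolve_volume(p, split, p.height)
            assert parts == pytest.approx(total, rel=1e-9)

    def test_interval_outside_support_raises(self, cylinder_profile):
        with pytest.raises(RangeError):
            revolve_volume(cylinder_profile, 0.0, 600.0)
        with pytest.raises(RangeError):
            revolve_volume(cylinder_profile, 300.0, 100.0)

    @given(split=st.floats(1.0, 899.0))
    @settings(max_examples=25, deadline=None)
    def test_additivity_property(self, split):
        p = shape_profile(DEFAULT_SHAPES["candlelit"], 901)
        total = revolve_volume(p)
        assert revolve_volume(p, 0, split) + revolve_volume(p, split, 900.0) == \
            pytest.approx(total, rel=1e-9)


class TestApplySwell:
    def test_height_increment(self):
        p = shape_profile(ShapeParams("conical", 900.0, 150.0))
        swollen = apply_swell(p, SwellIncrement(150.0, 75.0))
        assert swollen.height == pytest.approx(1050.0)
        # base diameter 300 -> 375
        assert 2 * swollen.r[-1] == pytest.approx(375.0)

    def test_zero_increment_is_identity(self, default_profiles):
        p = default_profiles["candlelit"]
        same = apply_swell(p, SwellIncrement(0.0, 0.0))
        np.testing.assert_array_equal(same.x, p.x)
        np.testing.assert_array_equal(same.r, p.r)

    def test_volume_never_shrinks(self, default_profiles):
        for p in default_profiles.values():
            assert revolve_volume(apply_swell(p, DEFAULT_SWELL)) >= revolve_volume(p)


class TestBandVolumeFraction:
    def test_full_coverage_is_one(self, cylinder_profile):
        band = DepthBand(0.0, 500.0, uninserted_offset=0.0)
        assert band_volume_fraction(cylinder_profile, band) == pytest.approx(1.0)

    def test_zero_overlap_is_zero(self, cylinder_profile):
        band = DepthBand(600.0, 700.0, uninserted_offset=0.0)
        assert band_volume_fraction(cylinder_profile, band) == 0.0

    def test_uniform_cylinder_deepest_half(self, cylinder_profile):
        band = DepthBand(0.0, 250.0, uninserted_offset=0.0)
        # depths [0, 250] correspond to the shallow (base) half; the deepest
        # half is depths [250, 500]
        deep = DepthBand(250.0, 500.0, uninserted_offset=0.0)
        assert band_volume_fraction(cylinder_profile, deep) == pytest.approx(0.5)
        assert band_volume_fraction(cylinder_profile, band) == pytest.approx(0.5)

    def test_band_beyond_inserted_length_returns_zero(self, cylinder_profile):
        band = DepthBand(900.0, 1000.0, uninserted_offset=100.0)
        assert band_volume_fraction(cylinder_profile, band) == 0.0

    def test_additive_over_disjoint_bands(self, swollen_profiles):
        p = swollen_profiles["candlelit"]
        # disjoint bands: fractions add to the union's fraction
        parts = [band_volume_fraction(p, DepthBand(a, b, 100.0))
                 for a, b in [(300.0, 420.0), (420.0, 700.0)]]
        union = band_volume_fraction(p, DepthBand(300.0, 700.0, 100.0))
        assert sum(parts) == pytest.approx(union, rel=1e-9)
        # bands tiling the whole needle (fully inserted) sum to 1
        tiles = np.linspace(0.0, p.height, 7)
        fracs = [band_volume_fraction(p, DepthBand(a, b, 0.0))
                 for a, b in zip(tiles[:-1], tiles[1:])]
        assert sum(fracs) == pytest.approx(1.0, rel=1e-9)

    def test_post_swell_ordering_across_scs_band_midpoints(self, swollen_profiles):
        """Candlelit > conical > funnel in-band fraction for every band
        midpoint in the 400-600 um suprachoroidal scoring range."""
        for mid in np.arange(400.0, 600.1, 10.0):
            band = DepthBand(mid - 50.0, mid + 50.0, 100.0)
            f = {name: band_volume_fraction(p, band)
                 for name, p in swollen_profiles.items()}
            assert f["candlelit"] > f["conical"] > f["funnel"], (mid, f)

    def test_swelling_never_reduces_candlelit_in_band_volume(self, default_profiles,
                                                             swollen_profiles):
        for mid in np.arange(400.0, 600.1, 10.0):
            band = DepthBand(mid - 50.0, mid + 50.0, 100.0)
            assert band_volume(swollen_profiles["candlelit"], band) >= \
                band_volume(default_profiles["candlelit"], band)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValidationError):
            DepthBand(550.0, 450.0)
        with pytest.raises(ValidationError):
            DepthBand(-10.0, 450.0)


class TestPercentVolumeChange:
    @pytest.mark.parametrize("v0,vt,expected", [
        (1.0, 1.0, 0.0),
        (1.0, 11.94, 1094.0),
        (2.0, 3.0, 50.0),
    ])
    def test_examples(self, v0, vt, expected):
        assert percent_volume_change(v0, vt) == pytest.approx(expected)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValidationError):
            percent_volume_change(0.0, 1.0)


class TestFitProfileCurve:
    def test_interpolates_landmarks_without_negative_radii(self):
        x = np.array([0.0, 100.0, 250.0, 400.0, 900.0])
        r = np.array([0.0, 120.0, 177.0, 130.0, 130.0])
        p = fit_profile_curve(x, r)
        assert np.all(p.r >= 0)
        np.testing.assert_allclose(p.radius_at(x), r, atol=1e-9)
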