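"""Vegetation-index formulas, compositing, and gap filling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lspheno as lp
from lspheno.indices import COMPOSITE_START_DOY, N_COMPOSITES


class TestEVI:
    def test_hand_computed_value(self):
        # 2.5*(0.40-0.10)/(0.40+0.6-0.375+1) = 0.75/1.625
        assert lp.compute_evi(0.40, 0.10, 0.05) == pytest.approx(
            0.75 / 1.625, abs=1e-12)

    def test_zero_when_nir_equals_red(self):
        assert lp.compute_evi(0.3, 0.3, 0.1) == pytest.approx(0.0)

    def test_denominator_guard_band(self):
        # blue=0.16: denominator 0.1+0.6-1.2+1 = 0.5 -> EVI 0
        assert lp.compute_evi(0.1, 0.1, 0.16) == pytest.approx(0.0)
        # blue=0.227: denominator 0.1+0.6-1.7025+1 = -0.0025 -> missing
        assert np.isnan(lp.compute_evi(0.1, 0.1, 0.227))

    def test_missing_propagates(self):
        assert np.isnan(lp.compute_evi(np.nan, 0.1, 0.05))
        out = lp.compute_evi(np.array([0.4, np.nan]), np.array([0.1, 0.1]),
                             np.array([0.05, 0.05]))
        assert np.isfinite(out[0]) and np.isnan(out[1])


class TestKNDVI:
    def test_hand_computed_value(self):
        # NDVI = 0.3/0.5 = 0.6 -> tanh(0.36)
        assert lp.compute_kndvi(0.40, 0.10) == pytest.approx(
            math.tanh(0.36), abs=1e-12)

    def test_zero_when_nir_equals_red(self):
        assert lp.compute_kndvi(0.25, 0.25) == pytest.approx(0.0)

    def test_vegetation_upper_bound_is_tanh_one(self):
        # NDVI -> 1 limit: kNDVI approaches tanh(1) from below
        assert lp.compute_kndvi(0.9, 1e-9) < math.tanh(1.0)
        assert lp.compute_kndvi(0.9, 1e-9) == pytest.approx(
            math.tanh(1.0), abs=1e-6)

    def test_zero_sum_is_missing(self):
        assert np.isnan(lp.compute_kndvi(0.0, 0.0))

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(nir=st.floats(0.001, 1.0), red=st.floats(0.001, 1.0))
    def test_default_sigma_identity_with_tanh_ndvi_squared(self, nir, red):
        ndvi = (nir - red) / (nir + red)
        assert lp.compute_kndvi(nir, red) == pytest.approx(
            math.tanh(ndvi ** 2), abs=1e-12)


class TestDVI:
    def test_subtraction_and_missing(self):
        assert lp.compute_dvi(0.4, 0.1) == pytest.approx(0.3)
        assert lp.compute_dvi(0.2, 0.2) == 0.0
        assert np.isnan(lp.compute_dvi(np.nan, 0.1))


class TestPPIGain:
    def test_overhead_sun_direct_beam(self):
        # (0.25/0.5) * (1.8/0.2) = 4.5
        assert lp.ppi_gain_k(0.0, 0.0, 0.5, 0.8) == pytest.approx(4.5)

    def test_fully_diffuse_is_independent_of_g(self):
        k1 = lp.ppi_gain_k(0.3, 1.0, 0.5, 0.6)
        k2 = lp.ppi_gain_k(0.3, 1.0, 5.0, 0.6)
        assert k1 == pytest.approx(k2)
        assert k1 == pytest.approx(0.25 * 1.6 / 0.4)

    def test_sparse_canopy_value(self):
        assert lp.ppi_gain_k(0.0, 0.0, 0.5, 0.2) == pytest.approx(0.75)

    def test_m_at_or_above_one_rejected(self):
        with pytest.raises(ValueError, match="must be < 1"):
            lp.ppi_gain_k(0.0, 0.0, 0.5, 1.0)


class TestPPI:
    def test_zero_at_bare_soil(self):
        p = lp.PPIParams(M=0.7, theta=0.0)
        assert lp.compute_ppi(0.09, p) == pytest.approx(0.0)

    def test_hand_computed_value_with_explicit_gain(self):
        p = lp.PPIParams(M=0.7, DVIs=0.09, theta=0.0)
        expected = -0.4 * math.log(0.2 / 0.61)
        assert lp.compute_ppi(0.5, p, K=0.4) == pytest.approx(
            expected, abs=1e-9)

    def test_clamp_caps_at_finite_value(self):
        p = lp.PPIParams(M=0.7, DVIs=0.09, theta=0.0, eps=0.04)
        cap = lp.compute_ppi(0.7, p, K=1.0)
        assert cap == pytest.approx(-math.log(0.04 / 0.61), abs=1e-9)
        assert lp.compute_ppi(0.95, p, K=1.0) == pytest.approx(cap)

    def test_monotone_in_dvi(self):
        p = lp.PPIParams(M=0.7, theta=0.3)
        dvi = np.linspace(0.0, 0.75, 200)
        ppi = lp.compute_ppi(dvi, p)
        assert np.all(np.diff(ppi) >= -1e-12)
        assert np.all(ppi >= 0)

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            lp.compute_ppi(0.3, lp.PPIParams(M=1.2))
        with pytest.raises(ValueError):
            lp.compute_ppi(0.3, lp.PPIParams(M=0.7, dc=1.5))


class TestSolarZenith:
    def test_subsolar_latitude_gives_zero(self):
        decl = 23.45 * math.sin(2 * math.pi * (284 + 172) / 365)
        assert lp.solar_zenith_noon(decl, 172) == pytest.approx(0.0, abs=1e-12)

    def test_summer_and_winter_solstice_values(self):
        decl = 23.45 * math.sin(2 * math.pi * (284 + 172) / 365)
        assert lp.solar_zenith_noon(35.0, 172) == pytest.approx(
            math.radians(35.0 - decl), abs=1e-12)
        decl_w = 23.45 * math.sin(2 * math.pi * (284 + 355) / 365)
        assert math.degrees(lp.solar_zenith_noon(35.0, 355)) == pytest.approx(
            35.0 - decl_w, abs=0.05)

    def test_out_of_range_inputs(self):
        with pytest.raises(ValueError):
            lp.solar_zenith_noon(95.0, 100)
        with pytest.raises(ValueError):
            lp.solar_zenith_noon(35.0, 0)


class TestComposite8Day:
    def test_mean_of_full_good_window(self):
        vals = np.full(365, np.nan)
        vals[:8] = np.arange(1.0, 9.0)
        good = np.zeros(365, bool)
        good[:8] = True
        comp, w = lp.composite_8day(vals, np.arange(1, 366), good)
        assert comp[0] == pytest.approx(4.5)
        assert w[0] == pytest.approx(1.0)
        assert comp.shape == (N_COMPOSITES,)

    def test_masked_mean_and_weight(self):
        vals = np.full(365, np.nan)
        vals[:8] = [9, 9, 9, 9, 2, 2, 2, 2]
        good = np.zeros(365, bool)
        good[4:8] = True
        comp, w = lp.composite_8day(vals, np.arange(1, 366), good)
        assert comp[0] == pytest.approx(2.0)
        assert w[0] == pytest.approx(0.5)

    def test_all_poor_window_is_missing_with_zero_weight(self):
        vals = np.ones(365)
        good = np.zeros(365, bool)
        comp, w = lp.composite_8day(vals, np.arange(1, 366), good)
        assert np.all(np.isnan(comp))
        assert np.all(w == 0)

    def test_grid_has_46_windows_starting_every_8_days(self):
        assert len(COMPOSITE_START_DOY) == 46
        assert COMPOSITE_START_DOY[0] == 1
        assert COMPOSITE_START_DOY[-1] == 361
        assert np.all(np.diff(COMPOSITE_START_DOY) == 8)

    def test_composite_ignores_missing_days(self):
        # adding extra missing/poor days never changes a composite
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, 365)
        good = rng.random(365) < 0.6
        c1, _ = lp.composite_8day(vals, np.arange(1, 366), good)
        vals2 = np.where(good, vals, np.nan)
        c2, _ = lp.composite_8day(vals2, np.arange(1, 366),
                                  np.ones(365, bool))
        np.testing.assert_allclose(c1, c2)


class TestFillLeadingGap:
    def test_constant_climatology(self):
        s = np.full((3, 46), 0.2)
        s[0, :7] = np.nan
        filled, mask = lp.fill_leading_gap(s)
        np.testing.assert_allclose(filled[0, :7], 0.2)
        assert mask[0, :7].all() and not mask[0, 7:].any()

    def test_no_gap_is_identity(self):
        s = np.random.default_rng(1).uniform(0, 1, (3, 46))
        filled, mask = lp.fill_leading_gap(s)
        np.testing.assert_array_equal(filled, s)
        assert not mask.any()

    def test_mean_of_later_years(self):
        s = np.full((3, 46), 0.5)
        s[0, 0] = np.nan
        s[1, 0], s[2, 0] = 0.1, 0.3
        filled, _ = lp.fill_leading_gap(s)
        assert filled[0, 0] == pytest.approx(0.2)

    def test_interior_gaps_untouched(self):
        s = np.full((3, 46), 0.5)
        s[0, 10] = np.nan  # after first valid composite: not a leading gap
        filled, mask = lp.fill_leading_gap(s)
        assert np.isnan(filled[0, 10]) and not mask.any()

    def test_unfillable_position_warns_and_stays_missing(self):
        s = np.full((2, 46), 0.5)
        s[0, 0] = np.nan
        s[1, 0] = np.nan
        with pytest.warns(UserWarning, match="remain missing"):
            filled, _ = lp.fill_leading_gap(s)
        assert np.isnan(filled[0, 0])


class TestPerPixelMaxDVI:
    def test_simple_maximum(self):
        assert lp.per_pixel_max_dvi(np.array([0.1, 0.5, 0.3])) == \
            pytest.approx(0.5)

    def test_all_missing_marks_non_vegetated(self):
        assert np.isnan(lp.per_pixel_max_dvi(np.full(5, np.nan)))

    def test_below_soil_marks_non_vegetated(self):
        assert np.isnan(lp.per_pixel_max_dvi(np.array([0.01, 0.05])))

    def test_matches_generator_algebra_on_clean_scene(self):
        # peak LAI 3 with extinction 0.5: M = 0.7 - 0.61*exp(-1.5)
        cfg = lp.SceneConfig(
            ny=1, nx=1, years=(2005,), seed=0, jitter_sd=0.0,
            sos_gradient=0, eos_gradient=0, mx_gradient=0,
            base_truth=lp.TruthParams(mx_lai=3.0),
            optics=lp.Optics(c_lai2dvi=0.5),
            contamination=lp.Contamination(noise_sd=0.0, cloud_prob=0.0,
                                           snow_prob=0.0),
        )
        scene = lp.generate_scene(cfg)
        comp = lp.compute_vi_composites(scene.reflectance,
                                        index_names=("ppi",))
        expected = 0.7 - 0.61 * math.exp(-1.5)
        assert comp["m_grid"][0, 0] == pytest.approx(expected, abs=2e-3)
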