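"""Synthetic-scene generator: truth fields, LAI, reflectance, contamination,
GPP/SIF proxies, and the generator-level invariants."""

import math

import numpy as np
import pytest

import lspheno as lp
from lspheno.synthetic import DOY


class TestMakeTruth:
    def test_linear_trend_no_jitter_is_exact(self):
        cfg = lp.SceneConfig(
            ny=2, nx=2, years=tuple(range(2000, 2024)), jitter_sd=0.0,
            base_truth=lp.TruthParams(sos_trend=-0.5), seed=1)
        truth = lp.make_truth(cfg)
        delta = truth["sos"].sel(year=2023) - truth["sos"].sel(year=2000)
        np.testing.assert_allclose(delta.values, -11.5)

    def test_no_trend_no_jitter_identical_years(self):
        cfg = lp.SceneConfig(ny=3, nx=3, years=(2000, 2001, 2002),
                             jitter_sd=0.0, seed=1)
        truth = lp.make_truth(cfg)
        for v in truth.data_vars:
            for i in (1, 2):
                np.testing.assert_array_equal(truth[v].isel(year=i).values,
                                              truth[v].isel(year=0).values)

    def test_fixed_seed_bit_identical(self):
        cfg = lp.SceneConfig(ny=4, nx=4, years=(2000, 2001), seed=7)
        t1, t2 = lp.make_truth(cfg), lp.make_truth(cfg)
        assert t1.identical(t2)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError, match="at least one pixel"):
            lp.make_truth(lp.SceneConfig(ny=0, nx=4))

    def test_invalid_season_names_pixel_year(self):
        cfg = lp.SceneConfig(
            ny=2, nx=2, years=tuple(range(2000, 2030)), jitter_sd=0.0,
            base_truth=lp.TruthParams(sos_trend=+4.0, eos_trend=-4.0),
            seed=1)
        with pytest.raises(ValueError, match=r"pixel \(row=.*year"):
            lp.make_truth(cfg)

    def test_spatial_gradient_present(self):
        cfg = lp.SceneConfig(ny=5, nx=5, years=(2000,), jitter_sd=0.0,
                             sos_gradient=6.0, seed=1)
        truth = lp.make_truth(cfg)
        sos = truth["sos"].values[0]
        assert sos[-1, -1] - sos[0, 0] == pytest.approx(6.0)


class TestLaiSeries:
    def test_logistic_midpoint_at_sos(self):
        tr = lp.TruthParams(mn_lai=0.2, mx_lai=2.0, sos=130, rsp=0.2,
                            eos=280, rau=0.2)
        lai = lp.lai_series(tr, [130.0])
        assert lai[0] == pytest.approx((0.2 + 2.0) / 2, abs=1e-6)

    def test_asymptote_before_season(self):
        tr = lp.TruthParams()
        assert lp.lai_series(tr, [2.0])[0] == pytest.approx(tr.mn_lai,
                                                            abs=1e-6)

    def test_independent_arithmetic_near_peak(self):
        # evaluate both logistic terms by direct arithmetic
        tr = lp.TruthParams(mn_lai=0.2, mx_lai=3.0, sos=130, rsp=0.2,
                            eos=280, rau=0.1)
        s1 = 1 / (1 + math.exp(-0.2 * (205 - 130)))   # sigma(15)
        s2 = 1 / (1 + math.exp(0.1 * (205 - 280)))    # sigma(7.5)
        expected = 0.2 + 2.8 * (s1 + s2 - 1)          # = 2.99845...
        assert lp.lai_series(tr, [205.0])[0] == pytest.approx(expected,
                                                              abs=1e-9)
        assert expected == pytest.approx(3.0, abs=2e-3)

    def test_greendown_plateau_slope(self):
        tr = lp.TruthParams(mn_lai=0.2, mx_lai=2.0, sos=130, rsp=0.2,
                            eos=280, rau=0.2, plateau_slope=-0.01)
        flat = lp.TruthParams(mn_lai=0.2, mx_lai=2.0, sos=130, rsp=0.2,
                              eos=280, rau=0.2)
        t = np.array([200.0, 240.0])
        drop = lp.lai_series(flat, t) - lp.lai_series(tr, t)
        assert drop[1] > drop[0] > 0
        assert drop[1] == pytest.approx(0.01 * (240 - 130 - 10), rel=1e-6)


class TestReflectance:
    def test_bare_soil_dvi(self):
        b, r, n, dvi = lp.reflectance_from_lai(np.array([0.0]), lp.Optics())
        assert dvi[0] == pytest.approx(0.09)

    def test_closed_canopy_asymptote(self):
        _, _, _, dvi = lp.reflectance_from_lai(np.array([50.0]), lp.Optics())
        assert dvi[0] == pytest.approx(0.7, abs=1e-9)
        assert dvi[0] < 0.7

    def test_independent_arithmetic(self):
        opt = lp.Optics(M_true=0.7, DVIs_true=0.09, c_lai2dvi=0.5)
        _, _, _, dvi = lp.reflectance_from_lai(np.array([2.0]), opt)
        assert dvi[0] == pytest.approx(0.7 - 0.61 * math.exp(-1.0), abs=1e-12)

    def test_noise_free_dvi_is_invertible(self, clean_scene):
        refl = clean_scene.reflectance
        dvi = lp.compute_dvi(refl["nir"].values, refl["red"].values)
        opt = clean_scene.config.optics
        tr = clean_scene.truth.isel(year=0)
        lai = lp.synthetic._lai_fields(
            DOY.astype(float), tr["mn_lai"].values, tr["mx_lai"].values,
            tr["sos"].values, tr["rsp"].values, tr["eos"].values,
            tr["rau"].values, tr["plateau_slope"].values)
        expected = opt.M_true - (opt.M_true - opt.DVIs_true) * np.exp(
            -opt.c_lai2dvi * lai)
        np.testing.assert_allclose(dvi, expected, atol=1e-12)

    def test_negative_lai_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            lp.reflectance_from_lai(np.array([-0.1]), lp.Optics())


class TestContaminate:
    def test_zero_probabilities_identity(self, clean_scene):
        cfg = clean_scene.config
        out = lp.contaminate(clean_scene.reflectance, cfg)
        assert out.identical(clean_scene.reflectance)

    def test_full_cloud_full_qa_flags_everything(self, clean_scene):
        cfg = lp.SceneConfig(
            ny=4, nx=4, years=(2005,), seed=3,
            contamination=lp.Contamination(cloud_prob=1.0,
                                           cloud_qa_detect=1.0,
                                           snow_prob=0.0))
        out = lp.contaminate(clean_scene.reflectance, cfg)
        assert (out["qa"].values == 0).all()

    def test_cloud_bias_is_negative_in_dvi(self, clean_scene):
        # Monte-Carlo sign check over >= 1000 contaminated observations
        cfg = lp.SceneConfig(
            ny=4, nx=4, years=(2005,), seed=5,
            contamination=lp.Contamination(cloud_prob=1.0,
                                           cloud_vi_bias=-0.15,
                                           snow_prob=0.0))
        out = lp.contaminate(clean_scene.reflectance, cfg)
        dvi_clean = lp.compute_dvi(clean_scene.reflectance["nir"].values,
                                   clean_scene.reflectance["red"].values)
        dvi_cont = lp.compute_dvi(out["nir"].values, out["red"].values)
        assert dvi_clean.size >= 1000
        assert dvi_cont.mean() < dvi_clean.mean()
        assert dvi_clean.mean() - dvi_cont.mean() == pytest.approx(0.15,
                                                                   rel=0.15)

    def test_snow_collapses_dvi_inside_window_only(self, clean_scene):
        cfg = lp.SceneConfig(
            ny=4, nx=4, years=(2005,), seed=6,
            contamination=lp.Contamination(cloud_prob=0.0, snow_prob=1.0,
                                           snow_window=(335, 60)))
        out = lp.contaminate(clean_scene.reflectance, cfg)
        doy = out["doy"].values
        dvi = lp.compute_dvi(out["nir"].values, out["red"].values)
        in_win = (doy >= 335) | (doy <= 60)
        assert np.abs(dvi[in_win]).max() < 0.05
        assert out["red"].values[in_win].min() > 0.5
        mid = (doy > 100) & (doy < 300)
        assert out["qa"].values[mid].all()  # untouched outside the window

    def test_poor_qa_only_on_contaminated(self, small_scene):
        # every poor-QA observation departed from the clean value
        cfg = small_scene.config
        clean_cfg = lp.SceneConfig(
            **{**cfg.__dict__,
               "contamination": lp.Contamination(
                   noise_sd=cfg.contamination.noise_sd, cloud_prob=0.0,
                   snow_prob=0.0)})
        clean = lp.generate_scene(clean_cfg)
        poor = small_scene.reflectance["qa"].values == 0
        diff = np.abs(small_scene.reflectance["nir"].values
                      - clean.reflectance["nir"].values) + np.abs(
            small_scene.reflectance["red"].values
            - clean.reflectance["red"].values)
        assert (diff[poor] > 1e-12).all()


class TestSifGpp:
    def _decline_doy(self, series):
        d = np.diff(series)
        return DOY[1:][np.argmin(d)]

    def test_zero_lead_declines_with_lai(self):
        tr = lp.TruthParams()
        lai = lp.lai_series(tr, DOY.astype(float))
        cfg = lp.SifGppConfig(autumn_lead_days=0.0, noise_sd=0.0)
        gpp, sif = lp.simulate_sif_gpp(lai, tr.eos, tr.rau, cfg, DOY,
                                       sos=tr.sos)
        assert abs(self._decline_doy(sif) - self._decline_doy(lai)) <= 1

    def test_lead_shifts_gpp_decline_forward(self):
        tr = lp.TruthParams()
        lai = lp.lai_series(tr, DOY.astype(float))
        cfg = lp.SifGppConfig(autumn_lead_days=20.0, noise_sd=0.0)
        gpp, _ = lp.simulate_sif_gpp(lai, tr.eos, tr.rau, cfg, DOY,
                                     sos=tr.sos)
        lead = self._decline_doy(lai) - self._decline_doy(gpp)
        assert lead == pytest.approx(20, abs=2)

    def test_zero_lue_gives_zero_gpp(self):
        tr = lp.TruthParams()
        lai = lp.lai_series(tr, DOY.astype(float))
        cfg = lp.SifGppConfig(lue=0.0, noise_sd=0.0)
        gpp, sif = lp.simulate_sif_gpp(lai, tr.eos, tr.rau, cfg, DOY)
        assert np.all(gpp == 0)

    def test_lead_before_sos_rejected(self):
        tr = lp.TruthParams()
        lai = lp.lai_series(tr, DOY.astype(float))
        cfg = lp.SifGppConfig(autumn_lead_days=200.0)
        with pytest.raises(ValueError, match="before sos"):
            lp.simulate_sif_gpp(lai, tr.eos, tr.rau, cfg, DOY, sos=tr.sos)

    def test_series_non_negative(self, small_scene):
        assert (small_scene.gpp.values >= 0).all()
        assert (small_scene.sif.values >= 0).all()


class TestSceneInvariants:
    def test_determinism_bit_identical(self):
        cfg = lp.SceneConfig(ny=3, nx=3, years=(2000, 2001), seed=11)
        s1, s2 = lp.generate_scene(cfg), lp.generate_scene(cfg)
        assert s1.reflectance.identical(s2.reflectance)
        assert s1.truth.identical(s2.truth)
        np.testing.assert_array_equal(s1.sif.values, s2.sif.values)

    def test_reflectance_within_unit_interval(self, small_scene):
        for v in ("blue", "red", "nir"):
            vals = small_scene.reflectance[v].values
            assert vals.min() >= 0 and vals.max() <= 1

    def test_true_metric_ordering(self, small_scene):
        tm = small_scene.true_metrics
        assert (tm["ud"] < tm["sd"]).all()
        assert (tm["sd"] < tm["dd0"]).all()
        assert (tm["dd0"] < tm["rd"]).all()

    def test_ppi_linearity_hook(self, clean_scene):
        # with M = M_true the PPI transform inverts the generator exactly:
        # PPI = K * c_lai2dvi * LAI for any constant gain K
        refl = clean_scene.reflectance
        opt = clean_scene.config.optics
        dvi = lp.compute_dvi(refl["nir"].values, refl["red"].values)
        params = lp.PPIParams(M=opt.M_true, DVIs=opt.DVIs_true, theta=0.0,
                              eps=1e-12)
        ppi = lp.compute_ppi(dvi, params, K=1.7)
        tr = clean_scene.truth.isel(year=0)
        lai = lp.synthetic._lai_fields(
            DOY.astype(float), tr["mn_lai"].values, tr["mx_lai"].values,
            tr["sos"].values, tr["rsp"].values, tr["eos"].values,
            tr["rau"].values, tr["plateau_slope"].values)
        np.testing.assert_allclose(ppi, 1.7 * opt.c_lai2dvi * lai, atol=1e-9)

    def test_autumn_lead_structure(self, clean_scene):
        # GPP autumn inflection precedes the LAI one by autumn_lead_days
        lead_cfg = clean_scene.config.sif_gpp.autumn_lead_days
        gpp = clean_scene.gpp.values[:, 0, 0]
        tr = clean_scene.truth.isel(year=0)
        lai = lp.lai_series(
            lp.TruthParams(mn_lai=float(tr["mn_lai"][0, 0]),
                           mx_lai=float(tr["mx_lai"][0, 0]),
                           sos=float(tr["sos"][0, 0]),
                           rsp=float(tr["rsp"][0, 0]),
                           eos=float(tr["eos"][0, 0]),
                           rau=float(tr["rau"][0, 0])),
            DOY.astype(float))
        d_gpp = DOY[1:][np.argmin(np.diff(gpp))]
        d_lai = DOY[1:][np.argmin(np.diff(lai))]
        assert d_lai - d_gpp == pytest.approx(lead_cfg, abs=2)
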