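"""The synthetic scene generator: landscape, speckle model, optics, ROIs."""

import numpy as np
import pytest
from scipy import special

from sarwheat import (
    CLASS_CODES,
    CLASS_LABELS,
    SceneConfig,
    draw_samples,
    generate_landscape,
    render_optical,
    render_sar,
)
from sarwheat.preprocess import BackscatterStack, calibrate, temporal_mean


class TestGenerateLandscape:
    def test_pure_wheat_proportions(self):
        cfg = SceneConfig(
            seed=0,
            proportions={
                "winter_wheat": 1.0,
                "other_vegetation": 0.0,
                "building": 0.0,
                "water": 0.0,
            },
        )
        truth = generate_landscape(cfg)
        assert (truth.raster.values == CLASS_CODES["winter_wheat"]).all()

    def test_empirical_fractions_near_target(self):
        cfg = SceneConfig(seed=1)
        truth = generate_landscape(cfg)
        n = truth.raster.values.size
        for cls, p in cfg.proportions.items():
            frac = (truth.raster.values == CLASS_CODES[cls]).sum() / n
            assert abs(frac - p) < 0.12  # patchy landscape: generous band

    def test_deterministic_given_seed(self):
        a = generate_landscape(SceneConfig(seed=5))
        b = generate_landscape(SceneConfig(seed=5))
        np.testing.assert_array_equal(a.raster.values, b.raster.values)

    def test_patch_larger_than_grid_raises(self):
        from dataclasses import replace

        cfg = SceneConfig(seed=0)
        cfg = SceneConfig(
            grid=replace(cfg.grid, n_rows=4, n_cols=4), seed=0, min_patch=6
        )
        with pytest.raises(ValueError, match="min_patch"):
            generate_landscape(cfg)


class TestRenderSar:
    def test_noise_off_round_trip_recovers_means(self):
        cfg = SceneConfig(seed=2, speckle=False)
        truth = generate_landscape(cfg)
        scenes = render_sar(truth, cfg)
        s0 = scenes[0]  # first date, VH
        db = calibrate(s0)
        for cls in CLASS_LABELS:
            m = truth.raster.values == CLASS_CODES[cls]
            if not m.any():
                continue
            np.testing.assert_allclose(
                db.values[m], cfg.radiometry[cls]["VH"][0], rtol=1e-9
            )

    def test_gamma_speckle_moments(self):
        cfg = SceneConfig(seed=3)
        truth = generate_landscape(cfg)
        scenes = render_sar(truth, cfg)
        s0 = scenes[0]
        cls = "winter_wheat"
        m = truth.raster.values == CLASS_CODES[cls]
        mu_lin = 10 ** (cfg.radiometry[cls]["VH"][0] / 10.0)
        intensity = (s0.raster.values[m] / cfg.calib_A) ** 2
        n = intensity.size
        se = mu_lin / np.sqrt(cfg.enl * n)  # std of the mean of Gamma(L)
        assert abs(intensity.mean() - mu_lin) < 3 * se
        cv2 = intensity.var() / intensity.mean() ** 2
        assert cv2 == pytest.approx(1.0 / cfg.enl, rel=0.15)

    def test_dn_strictly_positive(self):
        cfg = SceneConfig(seed=4)
        truth = generate_landscape(cfg)
        for s in render_sar(truth, cfg):
            assert (s.raster.values[s.raster.valid_mask] > 0).all()

    def test_temporal_averaging_separates_classes(self):
        # two classes 6+ dB apart separate almost fully after 9-date
        # dB averaging
        cfg = SceneConfig(seed=5)
        truth = generate_landscape(cfg)
        scenes = [s for s in render_sar(truth, cfg) if s.polarization == "VH"]
        stack = BackscatterStack(
            "VH", [s.date for s in scenes], [calibrate(s) for s in scenes]
        )
        mean_db = temporal_mean(stack).values
        wheat = mean_db[truth.raster.values == CLASS_CODES["winter_wheat"]]
        building = mean_db[truth.raster.values == CLASS_CODES["building"]]
        cut = 0.5 * (np.median(wheat) + np.median(building))
        overlap = (wheat > cut).mean() + (building < cut).mean()
        assert overlap < 0.05

    def test_configured_shift_applied(self):
        cfg = SceneConfig(seed=6, shifts={1: (2, -1)})
        truth = generate_landscape(cfg)
        scenes = render_sar(truth, cfg)
        shifted = [s for s in scenes if s.date == cfg.dates[1]][0]
        assert not shifted.raster.valid_mask[0].any()  # exposed margin


class TestRenderOptical:
    def test_zero_std_exact_class_ndvi(self):
        cfg = SceneConfig(seed=7)
        for cls in cfg.optics:
            cfg.optics[cls]["red_std"] = 0.0
            cfg.optics[cls]["nir_std"] = 0.0
        truth = generate_landscape(cfg)
        opt = render_optical(truth, cfg)
        from sarwheat import ndvi

        idx = ndvi(opt).values
        o = cfg.optics["winter_wheat"]
        expected = (o["nir_mean"] - o["red_mean"]) / (o["nir_mean"] + o["red_mean"])
        m = truth.raster.values == CLASS_CODES["winter_wheat"]
        np.testing.assert_allclose(idx[m], expected, rtol=1e-12)

    def test_class_ndvi_means_match_delta_method(self):
        cfg = SceneConfig(seed=8)
        truth = generate_landscape(cfg)
        opt = render_optical(truth, cfg)
        from sarwheat import ndvi

        idx = ndvi(opt).values
        for cls in CLASS_LABELS:
            o = cfg.optics[cls]
            m = truth.raster.values == CLASS_CODES[cls]
            n = int(m.sum())
            if n < 100:
                continue
            r, s = o["red_mean"], o["nir_mean"]
            expected = (s - r) / (s + r)
            # delta-method std of ndvi from band stds
            d_nir = 2 * r / (s + r) ** 2
            d_red = -2 * s / (s + r) ** 2
            sd = np.sqrt(
                (d_nir * o["nir_std"]) ** 2 + (d_red * o["red_std"]) ** 2
            )
            assert abs(idx[m].mean() - expected) < 3 * sd / np.sqrt(n) + 1e-3

    def test_water_ndvi_negative(self):
        cfg = SceneConfig(seed=9)
        truth = generate_landscape(cfg)
        opt = render_optical(truth, cfg)
        from sarwheat import ndvi

        idx = ndvi(opt).values
        m = truth.raster.values == CLASS_CODES["water"]
        assert (idx[m] < 0).mean() > 0.99

    def test_ndvi_ordering_of_defaults(self):
        # other vegetation >> wheat > building > 0 > water
        cfg = SceneConfig(seed=10)
        means = {}
        for cls, o in cfg.optics.items():
            means[cls] = (o["nir_mean"] - o["red_mean"]) / (
                o["nir_mean"] + o["red_mean"]
            )
        assert (
            means["other_vegetation"]
            > means["winter_wheat"]
            > means["building"]
            > 0
            > means["water"]
        )


class TestDrawSamples:
    def test_default_counts_support_table_split(self):
        from sarwheat import split_samples

        cfg = SceneConfig(seed=11)
        truth = generate_landscape(cfg)
        samples = draw_samples(truth, seed=11)
        assert samples.class_counts() == {
            "winter_wheat": 60,
            "other_vegetation": 30,
            "building": 60,
            "water": 30,
        }
        train, valid = split_samples(samples, 0.7, seed=11)
        assert len(train) == 126 and len(valid) == 54

    def test_roi_purity(self):
        cfg = SceneConfig(seed=12)
        truth = generate_landscape(cfg)
        samples = draw_samples(truth, seed=12)
        for r in samples.regions:
            labels = truth.raster.values[r.pixels[:, 0], r.pixels[:, 1]]
            assert (labels == CLASS_CODES[r.class_label]).all()

    def test_deterministic(self):
        cfg = SceneConfig(seed=13)
        truth = generate_landscape(cfg)
        a = draw_samples(truth, seed=13)
        b = draw_samples(truth, seed=13)
        for ra, rb in zip(a.regions, b.regions):
            np.testing.assert_array_equal(ra.pixels, rb.pixels)

    def test_insufficient_area_raises(self):
        cfg = SceneConfig(
            seed=14,
            proportions={
                "winter_wheat": 0.99,
                "other_vegetation": 0.003,
                "building": 0.004,
                "water": 0.003,
            },
        )
        truth = generate_landscape(cfg)
        with pytest.raises(ValueError, match="insufficient pure area"):
            draw_samples(truth, per_class_counts={"water": 500}, seed=14)
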