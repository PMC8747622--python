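"""Pixel-wise inversion: masking, map prediction, rendering, statistics."""

import numpy as np
import pytest

from spadspec import (Hypercube, ModelSpec, SimConfig, calibrate, fit,
                      generate_dataset, generate_hypercube)
from spadspec.inversion import (SPADMap, leaf_mask, match_wavelengths,
                                predict_map, render_map, stats_frame)
from spadspec.synthetic import elliptical_leaf_mask


@pytest.fixture(scope="module")
def trained():
    """Model + config trained on a clean synthetic dataset."""
    cfg = SimConfig(n_samples=120, seed=30, noise_sd=0.002,
                    spectral_corr_length=0.0)
    ds = generate_dataset(cfg)
    model = fit(ds, ModelSpec("plsr", {"n_components": 5}),
                bands=list(cfg.informative_bands))
    return cfg, model


def _reflectance_cube(spad_field, mask, cfg):
    raw, white, dark, truth = generate_hypercube(spad_field, mask, cfg)
    return calibrate(raw, white, dark), truth


class TestLeafMask:
    def test_exact_recovery_zero_noise(self):
        cfg = SimConfig(seed=0, noise_sd=0.0)
        mask_true = elliptical_leaf_mask(20, 24)
        cube, _ = _reflectance_cube(np.full((20, 24), 55.0), mask_true, cfg)
        np.testing.assert_array_equal(leaf_mask(cube), mask_true)

    def test_noisy_recovery_high_jaccard(self):
        cfg = SimConfig(seed=5)  # default correlated noise
        mask_true = elliptical_leaf_mask(30, 30)
        cube, _ = _reflectance_cube(np.full((30, 30), 55.0), mask_true, cfg)
        m = leaf_mask(cube)
        jaccard = (m & mask_true).sum() / (m | mask_true).sum()
        assert jaccard >= 0.95

    def test_no_nir_band_rejected(self, rng):
        cube = Hypercube(rng.uniform(0, 1, (5, 5, 10)),
                         np.linspace(400, 700, 10))
        with pytest.raises(ValueError, match="750"):
            leaf_mask(cube)

    def test_all_background_cube_refused_downstream(self, trained):
        cfg, model = trained
        shape = (10, 10)
        cube, _ = _reflectance_cube(np.zeros(shape),
                                    np.zeros(shape, bool), cfg)
        with pytest.raises(ValueError, match="empty"):
            predict_map(cube, model)


class TestPredictMap:
    def test_constant_cube_gives_models_constant_prediction(self, trained):
        cfg, model = trained
        mask = elliptical_leaf_mask(16, 16)
        cube, _ = _reflectance_cube(np.full((16, 16), 58.0), mask,
                                    SimConfig(seed=1, noise_sd=0.0))
        smap = predict_map(cube, model, mask=mask)
        leaf_vals = smap.values[mask]
        spectrum = cube.data[mask][0][model.bands][None, :]
        expected = model.predict(spectrum)[0]
        np.testing.assert_allclose(leaf_vals, expected, atol=1e-9)
        assert np.isnan(smap.values[~mask]).all()

    def test_gradient_field_recovered(self, trained):
        from scipy import stats

        cfg, model = trained
        mask = elliptical_leaf_mask(40, 40)
        field = np.tile(np.linspace(40, 70, 40), (40, 1))
        cube, truth = _reflectance_cube(field, mask,
                                        SimConfig(seed=2, noise_sd=0.002,
                                                  spectral_corr_length=0.0))
        smap = predict_map(cube, model, mask=mask)
        rho = stats.spearmanr(smap.values[mask], truth[mask]).statistic
        assert rho >= 0.9

    def test_wavelength_mismatch_beyond_tolerance_rejected(self, trained):
        cfg, model = trained
        mask = elliptical_leaf_mask(8, 8)
        cube, _ = _reflectance_cube(np.full((8, 8), 50.0), mask,
                                    SimConfig(seed=3, n_bands=40))
        # 40-band grid spacing ~15 nm: selected wavelengths miss by > 1.8 nm
        with pytest.raises(ValueError, match="off-grid"):
            predict_map(cube, model, mask=mask)

    def test_match_wavelengths_nearest_neighbour(self):
        grid = np.linspace(400, 1000, 176)
        idx = match_wavelengths(grid, grid[[3, 99]] + 0.5)
        np.testing.assert_array_equal(idx, [3, 99])


class TestMapStatsAndRender:
    def test_stats_match_flat_array_computation(self, rng):
        mask = elliptical_leaf_mask(12, 12)
        values = np.where(mask, rng.uniform(40, 70, (12, 12)), np.nan)
        smap = SPADMap(values=values, mask=mask)
        flat = values[mask].ravel()
        assert smap.stats["min"] == flat.min()
        assert smap.stats["max"] == flat.max()
        assert smap.stats["mean"] == pytest.approx(flat.mean())
        assert smap.stats["std"] == pytest.approx(flat.std())
        assert smap.stats["min"] <= smap.stats["mean"] <= smap.stats["max"]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            SPADMap(values=np.zeros((4, 4)), mask=np.zeros((4, 4), bool))

    def test_single_value_map_uniform_colour(self, tmp_path):
        from PIL import Image

        mask = elliptical_leaf_mask(10, 10)
        smap = SPADMap(values=np.where(mask, 55.0, np.nan), mask=mask)
        _, color = render_map(smap, tmp_path / "m.png")
        rgb = np.asarray(Image.open(color))
        leaf_px = rgb[mask]
        assert (leaf_px == leaf_px[0]).all()

    def test_limits_map_to_palette_endpoints(self, tmp_path):
        from PIL import Image

        from spadspec.inversion import DEFAULT_PALETTE

        mask = np.ones((1, 2), bool)
        smap = SPADMap(values=np.array([[0.0, 80.0]]), mask=mask)
        _, color = render_map(smap, tmp_path / "e.png", vmin=0.0, vmax=80.0)
        rgb = np.asarray(Image.open(color))
        np.testing.assert_array_equal(rgb[0, 0], DEFAULT_PALETTE[0][1])
        np.testing.assert_array_equal(rgb[0, 1], DEFAULT_PALETTE[-1][1])

    def test_rerender_is_byte_identical(self, tmp_path, rng):
        mask = elliptical_leaf_mask(9, 9)
        smap = SPADMap(values=np.where(mask, rng.uniform(40, 70, (9, 9)),
                                       np.nan), mask=mask)
        g1, c1 = render_map(smap, tmp_path / "a.png")
        blob_g, blob_c = g1.read_bytes(), c1.read_bytes()
        g2, c2 = render_map(smap, tmp_path / "a.png")
        assert g2.read_bytes() == blob_g
        assert c2.read_bytes() == blob_c

    def test_stats_frame_schema(self, rng):
        mask = np.ones((3, 3), bool)
        m = SPADMap(values=rng.uniform(40, 60, (3, 3)), mask=mask)
        df = stats_frame({"lower": m})
        assert list(df.columns) == ["leaf", "min", "max", "mean", "std"]


def test_linear_model_roi_consistency(trained, rng):
    """For a linear model on a constant region, the pixel-mean prediction
    equals the prediction of the mean spectrum exactly."""
    from spadspec import ROI, extract_roi_spectra

    cfg, model = trained
    mask = np.ones((10, 10), bool)
    cube, _ = _reflectance_cube(np.full((10, 10), 52.0), mask,
                                SimConfig(seed=9, noise_sd=0.0))
    smap = predict_map(cube, model, mask=mask)
    _, combined = extract_roi_spectra(cube, [ROI(0, 10, 0, 10)])
    roi_pred = model.predict(combined[model.bands][None, :])[0]
    assert smap.values[mask].mean() == pytest.approx(roi_pred, abs=1e-9)
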