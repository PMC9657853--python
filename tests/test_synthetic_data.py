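import numpy as np
import pytest

from spectroleaf.errors import ContractError
from spectroleaf.evaluation import cross_correlation
from spectroleaf.hsi_io import nir_threshold_mask, roi_mean_spectrum
from spectroleaf.synthetic_data import (
    RESPONSES,
    SyntheticConfig,
    generate_cube,
    generate_leaf_spectrum,
    generate_solution_spectrum,
    generate_study,
)


class TestLeafSpectrum:
    def test_deterministic_without_noise(self, tub_config):
        cfg = SyntheticConfig.tub_default(noise_sd=0.0)
        z = cfg.response_ref + 10.0
        a = generate_leaf_spectrum(z, cfg, np.random.default_rng(1))
        b = generate_leaf_spectrum(z, cfg, np.random.default_rng(99))
        np.testing.assert_array_equal(a.values, b.values)

    def test_zero_effect_matrix_ignores_nutrients(self):
        cfg = SyntheticConfig.tub_default(
            noise_sd=0.0, effect_matrix=np.zeros((6, len(RESPONSES)))
        )
        a = generate_leaf_spectrum(cfg.response_ref, cfg, np.random.default_rng(0))
        b = generate_leaf_spectrum(cfg.response_ref * 1.8 + 3.0, cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(a.values, b.values)

    def test_chlorophyll_morphology(self, tub_config):
        cfg = SyntheticConfig.tub_default(noise_sd=0.0)
        spec = generate_leaf_spectrum(cfg.response_ref, cfg, np.random.default_rng(0))
        wl = cfg.grid.wavelengths_nm
        nir = spec.values[(wl >= 800) & (wl <= 900)].mean()
        blue = spec.values[(wl >= 400) & (wl <= 450)].mean()
        green = spec.values[(wl >= 540) & (wl <= 560)].mean()
        red = spec.values[(wl >= 620) & (wl <= 660)].mean()
        assert nir > blue  # NIR plateau above the blue plateau
        assert green > red  # green peak above the red trough

    def test_wrong_dimension_rejected(self, tub_config):
        with pytest.raises(ContractError):
            generate_leaf_spectrum(np.ones(4), tub_config, np.random.default_rng(0))


class TestSolutionSpectrum:
    def test_zero_ppm_flat_in_window(self):
        cfg = SyntheticConfig.tub_default(noise_sd=0.0)
        spec = generate_solution_spectrum(0.0, cfg, np.random.default_rng(0))
        wl = cfg.grid.wavelengths_nm
        window = (wl >= 390.57) & (wl <= 554.48)
        np.testing.assert_allclose(spec.values[window], cfg.water_baseline)

    def test_leaf_solution_correlation(self, tub_config):
        cfg = tub_config
        rng = np.random.default_rng(5)
        leaf = generate_leaf_spectrum(cfg.response_ref, cfg, rng)
        solution = generate_solution_spectrum(200.0, cfg, rng)
        r = cross_correlation(solution, leaf, (390.57, 554.48)).r_corr
        assert r >= 0.8

    def test_window_mean_monotone_in_n(self):
        cfg = SyntheticConfig.tub_default(noise_sd=0.0)
        wl = cfg.grid.wavelengths_nm
        window = (wl >= 390.57) & (wl <= 554.48)
        means = [
            generate_solution_spectrum(n, cfg, np.random.default_rng(0)).values[window].mean()
            for n in (50.0, 350.0)
        ]
        assert means[1] > means[0]

    def test_negative_ppm_rejected(self, tub_config):
        with pytest.raises(ContractError):
            generate_solution_spectrum(-1.0, tub_config, np.random.default_rng(0))


class TestGenerateCube:
    def test_noise_free_round_trip(self, tub_config):
        spec = generate_leaf_spectrum(
            tub_config.response_ref, tub_config, np.random.default_rng(0)
        )
        cube = generate_cube(spec, (16, 16), 0.0, np.random.default_rng(1))
        # identical pixels: the mean reproduces the spectrum to summation rounding
        np.testing.assert_allclose(roi_mean_spectrum(cube).values, spec.values, rtol=1e-13)

    def test_mean_within_standard_error(self, tub_config):
        spec = generate_leaf_spectrum(
            tub_config.response_ref, tub_config, np.random.default_rng(0)
        )
        cube = generate_cube(spec, (32, 32), 0.01, np.random.default_rng(2))
        n_masked = cube.roi_mask.sum()
        se = 0.01 / np.sqrt(n_masked)
        errors = np.abs(roi_mean_spectrum(cube).values - spec.values)
        # per-band errors behave like N(0, se): the bulk stays within 3 se and
        # across 462 bands nothing should stray past 5 se
        assert np.quantile(errors, 0.99) < 3.0 * se
        assert errors.max() < 5.0 * se

    def test_mask_covers_about_forty_percent(self, tub_config):
        spec = generate_leaf_spectrum(
            tub_config.response_ref, tub_config, np.random.default_rng(0)
        )
        cube = generate_cube(spec, (32, 32), 0.0, np.random.default_rng(0))
        frac = cube.roi_mask.mean()
        assert 0.3 < frac < 0.5

    def test_nir_helper_recovers_true_mask(self, tub_config):
        spec = generate_leaf_spectrum(
            tub_config.response_ref, tub_config, np.random.default_rng(0)
        )
        cube = generate_cube(spec, (24, 24), 0.005, np.random.default_rng(3))
        np.testing.assert_array_equal(nir_threshold_mask(cube, threshold=0.3), cube.roi_mask)

    def test_bad_shape_rejected(self, tub_config):
        spec = generate_leaf_spectrum(
            tub_config.response_ref, tub_config, np.random.default_rng(0)
        )
        with pytest.raises(ContractError):
            generate_cube(spec, (0, 5), 0.0, np.random.default_rng(0))


class TestGenerateStudy:
    def test_tub_cardinality(self, tub_study):
        assert len(tub_study.samples) == 4 * 8 * 4
        assert len(tub_study.spectra) == 128
        assert len(tub_study.solution_spectra) == 8

    def test_nft_cardinality(self, nft_config):
        study = generate_study(nft_config)
        assert len(study.samples) == 4 * 4 * 4

    def test_grid_matches_instrument(self, tub_study):
        grid = tub_study.config.grid
        assert grid.n_bands == 462
        assert grid.wavelengths_nm[0] == pytest.approx(390.57)
        assert grid.wavelengths_nm[-1] == pytest.approx(1008.6)

    def test_seed_reproducibility(self):
        a = generate_study(SyntheticConfig.tub_default(seed=123))
        b = generate_study(SyntheticConfig.tub_default(seed=123))
        assert a.samples.equals(b.samples)
        for sa, sb in zip(a.spectra, b.spectra):
            np.testing.assert_array_equal(sa.values, sb.values)

    def test_replicate_growth_preserves_existing_draws(self):
        small = generate_study(SyntheticConfig.tub_default(seed=3, n_replicates=2))
        large = generate_study(SyntheticConfig.tub_default(seed=3, n_replicates=4))
        small_map = {s.label: s.values for s in small.spectra}
        large_map = {s.label: s.values for s in large.spectra}
        for label, values in small_map.items():
            np.testing.assert_array_equal(large_map[label], values)

    def test_no3_nondecreasing_in_applied_n(self, tub_study):
        means = (
            tub_study.samples[tub_study.samples["applied_N_ppm"] >= 50]
            .groupby("applied_N_ppm")["NO3_ppm"]
            .mean()
        )
        assert np.all(np.diff(means.to_numpy()) >= -1e-9)

    def test_table_passes_validation(self, tub_study):
        from spectroleaf.hsi_io import validate_sample_table

        validate_sample_table(tub_study.samples)

    def test_cubes_emitted_when_configured(self):
        cfg = SyntheticConfig.tub_default(
            seed=1, cultivars=("Rex RZ",), treatments_ppm=(50, 200), n_replicates=1,
            cube_shape=(8, 8),
        )
        study = generate_study(cfg)
        assert len(study.cubes) == 2
        cube = next(iter(study.cubes.values()))
        assert cube.reflectance.shape == (8, 8, 462)

    def test_ground_truth_round_trip(self, tub_study, tmp_path):
        from spectroleaf.synthetic_data import GroundTruth

        path = str(tmp_path / "gt.json")
        tub_study.ground_truth.to_json(path)
        back = GroundTruth.from_json(path)
        np.testing.assert_array_equal(
            back.informative_band_indices, tub_study.ground_truth.informative_band_indices
        )
        for name in RESPONSES:
            np.testing.assert_allclose(
                back.true_beta[name], tub_study.ground_truth.true_beta[name]
            )


class TestEndToEndRecovery:
    def test_plsr_recovers_truth(self, tub_study):
        from spectroleaf.evaluation import r_squared
        from spectroleaf.models import (
            PredictorMatrix, ResponseVector, extract_regression, fit_plsr, predict,
        )
        from spectroleaf.preprocess import smooth_moving_average

        cfg = tub_study.config
        info = tub_study.ground_truth.informative_band_indices
        smoothed = np.vstack(
            [smooth_moving_average(s, cfg.smoothing_window).values for s in tub_study.spectra]
        )
        X = PredictorMatrix(
            X=smoothed[:, info],
            band_nm=cfg.grid.wavelengths_nm[info],
            sample_ids=[s.label for s in tub_study.spectra],
        )
        table = tub_study.samples.set_index("sample_id")
        for response in RESPONSES:
            y = ResponseVector(table.loc[X.sample_ids, response].to_numpy(), response)
            coeffs = extract_regression(fit_plsr(X, y, 6))
            corr = np.corrcoef(coeffs.beta, tub_study.ground_truth.true_beta[response])[0, 1]
            assert corr >= 0.99, f"{response}: beta correlation {corr:.4f}"
            if response == "NO3_ppm":
                assert r_squared(y, predict(coeffs, X)) >= 0.95
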