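"""Calibration, filtering, segmentation and preprocessing contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from seedhsi import (CubeState, PreprocessMethod, PreprocessSpec,
                     ReferenceFrames, SpectralCube, calibrate_reflectance,
                     extract_mean_spectra, median_filter3, apply_preprocess,
                     segment_seeds)
from seedhsi.synth import default_grid, render_scene


def _refl_cube(values):
    grid = default_grid(values.shape[2])
    return SpectralCube(values, grid, CubeState.REFLECTANCE, [])


class TestCalibration:
    @pytest.fixture()
    def refs(self):
        rng = np.random.default_rng(0)
        dark = 100 + rng.random((10, 16))
        return ReferenceFrames(dark + 1000 + 100 * rng.random((10, 16)), dark)

    def _raw(self, values2d, refs):
        grid = default_grid(16)
        return SpectralCube(np.broadcast_to(values2d, (5, 10, 16)).copy(),
                            grid, CubeState.RAW, [])

    def test_white_maps_to_one(self, refs):
        cal = calibrate_reflectance(self._raw(refs.white, refs), refs)
        np.testing.assert_allclose(cal.values, 1.0)
        assert cal.state is CubeState.REFLECTANCE

    def test_dark_maps_to_zero(self, refs):
        cal = calibrate_reflectance(self._raw(refs.dark, refs), refs)
        np.testing.assert_allclose(cal.values, 0.0)

    def test_midpoint_maps_to_half(self, refs):
        mid = (refs.white + refs.dark) / 2
        cal = calibrate_reflectance(self._raw(mid, refs), refs)
        np.testing.assert_allclose(cal.values, 0.5)

    def test_clipping_bounds_output(self, refs):
        hot = refs.white * 3
        cal = calibrate_reflectance(self._raw(hot, refs), refs)
        assert cal.values.max() <= 1.2

    def test_nonpositive_span_raises_with_location(self, refs):
        refs.white[3, 7] = refs.dark[3, 7]
        with pytest.raises(ValueError, match="pixel 3, band 7"):
            calibrate_reflectance(self._raw(refs.dark, refs), refs)

    def test_requires_raw_state(self, refs):
        cube = _refl_cube(np.full((5, 10, 16), 0.5))
        with pytest.raises(ValueError, match="raw"):
            calibrate_reflectance(cube, refs)


class TestMedianFilter:
    def test_constant_band_unchanged(self):
        cube = _refl_cube(np.full((6, 6, 8), 0.4))
        np.testing.assert_allclose(median_filter3(cube).values, 0.4)

    def test_single_impulse_removed(self):
        values = np.zeros((7, 7, 8))
        values[3, 3, :] = 10.0
        out = median_filter3(_refl_cube(values))
        assert np.all(out.values[3, 3, :] == 0.0)

    def test_matches_bruteforce_interior_median(self):
        rng = np.random.default_rng(1)
        values = rng.random((9, 11, 8))
        out = median_filter3(_refl_cube(values)).values
        for b in range(8):
            for i in range(1, 8):
                for j in range(1, 10):
                    window = values[i - 1:i + 2, j - 1:j + 2, b]
                    assert out[i, j, b] == np.median(window)

    def test_too_small_extent_raises(self):
        with pytest.raises(ValueError, match="3x3"):
            median_filter3(_refl_cube(np.zeros((2, 10, 8))))


class TestSegmentation:
    def test_noise_free_scene_recovers_truth_footprints(self, spec, config):
        cube, refs, truth = render_scene(5, spec, rng=21, scatter_sigma=0.0,
                                         baseline_sigma=0.0, tilt_sigma=0.0,
                                         noise_counts=0.0)
        cal = calibrate_reflectance(cube, refs)
        regions, _ = segment_seeds(cal, config.seg_threshold, config.min_area)
        assert len(regions) == 5
        truth_sets = [set(zip(s.footprint[0].tolist(), s.footprint[1].tolist()))
                      for s in truth.seeds]
        for r in regions:
            got = set(zip(r.pixels[0].tolist(), r.pixels[1].tolist()))
            assert got in truth_sets

    def test_all_background_gives_empty_list(self, config):
        cube = _refl_cube(np.full((20, 20, 8), 0.05))
        regions, mask = segment_seeds(cube, config.seg_threshold,
                                      config.min_area)
        assert regions == [] and not mask.any()

    def test_small_speck_removed_by_area_opening(self):
        values = np.full((20, 20, 8), 0.05)
        values[4, 4:7, :] = 0.9   # 3-pixel speck
        regions, _ = segment_seeds(_refl_cube(values), 0.2, min_area=20)
        assert regions == []

    def test_regions_in_scanline_order(self, small_scene, config):
        cube, refs, _ = small_scene
        cal = calibrate_reflectance(cube, refs)
        regions, _ = segment_seeds(cal, config.seg_threshold, config.min_area)
        firsts = [r.bbox[0] for r in regions]
        assert firsts == sorted(firsts)


class TestExtractMeanSpectra:
    def test_identical_pixels_return_that_spectrum(self, config):
        values = np.full((10, 10, 8), 0.05)
        s = np.linspace(0.3, 0.9, 8)
        values[2:8, 2:8, :] = s
        cube = _refl_cube(values)
        regions, _ = segment_seeds(cube, 0.2, min_area=4)
        table = extract_mean_spectra(cube, regions)
        np.testing.assert_allclose(table.spectra[0], s)

    def test_matches_bruteforce_pixel_loop(self, small_scene, config):
        cube, refs, _ = small_scene
        cal = calibrate_reflectance(cube, refs)
        regions, _ = segment_seeds(cal, config.seg_threshold, config.min_area)
        table = extract_mean_spectra(cal, regions)
        for row, r in zip(table.spectra, regions):
            acc = np.zeros(cal.n_bands)
            for l, p in zip(r.pixels[0], r.pixels[1]):
                acc += cal.values[l, p, :]
            np.testing.assert_allclose(row, acc / r.area, atol=1e-12)

    def test_two_pixel_region_averages(self):
        from seedhsi.prep import SeedRegion
        values = np.zeros((2, 2, 8))
        u, v = np.linspace(0, 1, 8), np.linspace(1, 0, 8)
        values[0, 0], values[0, 1] = u, v
        region = SeedRegion("R0", (np.array([0, 0]), np.array([0, 1])),
                            (0, 1, 0, 2), 2, (0.0, 0.5))
        table = extract_mean_spectra(_refl_cube(values), [region])
        np.testing.assert_allclose(table.spectra[0], (u + v) / 2)


class TestPreprocess:
    def test_range_norm_example(self):
        spec = PreprocessSpec(PreprocessMethod.RANGE_NORM)
        out = apply_preprocess(spec, np.array([[2.0, 4.0, 6.0]]))
        np.testing.assert_allclose(out, [[0.0, 0.5, 1.0]])

    def test_snv_example(self):
        spec = PreprocessSpec(PreprocessMethod.SNV)
        out = apply_preprocess(spec, np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]])

    def test_msc_inverts_affine_distortion(self):
        ref = np.linspace(0.2, 0.8, 24)
        spec = PreprocessSpec(PreprocessMethod.MSC, msc_reference=ref)
        out = apply_preprocess(spec, (2.0 * ref + 5.0)[None, :])
        np.testing.assert_allclose(out[0], ref, atol=1e-12)

    def test_msc_leaves_reference_row_unchanged(self):
        rng = np.random.default_rng(3)
        X = rng.random((10, 24)) + np.linspace(0, 1, 24)
        ref = X.mean(axis=0)
        spec = PreprocessSpec(PreprocessMethod.MSC, msc_reference=ref)
        out = apply_preprocess(spec, ref[None, :])
        np.testing.assert_allclose(out[0], ref, atol=1e-12)

    def test_sg1_of_line_is_slope_per_band(self):
        spec = PreprocessSpec(PreprocessMethod.SG1)
        row = (0.7 + 0.003 * np.arange(40))[None, :]
        out = apply_preprocess(spec, row)
        np.testing.assert_allclose(out, 0.003, atol=1e-12)

    def test_sg2_of_line_is_zero(self):
        spec = PreprocessSpec(PreprocessMethod.SG2)
        row = (0.7 + 0.003 * np.arange(40))[None, :]
        np.testing.assert_allclose(apply_preprocess(spec, row), 0.0,
                                   atol=1e-12)

    def test_sg2_of_quadratic_matches_analytic(self):
        spec = PreprocessSpec(PreprocessMethod.SG2)
        i = np.arange(60, dtype=float)
        row = (0.1 + 0.02 * i + 0.005 * i ** 2)[None, :]
        out = apply_preprocess(spec, row)
        # d2/di2 = 2 * 0.005 everywhere for an exact quadratic
        np.testing.assert_allclose(out[0, 5:-5], 0.01, atol=1e-8)

    @pytest.mark.parametrize("method,row", [
        (PreprocessMethod.SNV, [1.0, 1.0, 1.0]),
        (PreprocessMethod.RANGE_NORM, [2.0, 2.0, 2.0]),
        (PreprocessMethod.MAX_NORM, [-1.0, -2.0, 0.0]),
    ])
    def test_degenerate_rows_raise(self, method, row):
        with pytest.raises(ValueError):
            apply_preprocess(PreprocessSpec(method), np.array([row]))

    def test_even_sg_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            PreprocessSpec(PreprocessMethod.SG1, sg_window=10)

    def test_msc_reference_required_iff_msc(self):
        with pytest.raises(ValueError):
            PreprocessSpec(PreprocessMethod.MSC)
        with pytest.raises(ValueError):
            PreprocessSpec(PreprocessMethod.SNV,
                           msc_reference=np.ones(8))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (3, 16),
                  elements=st.floats(0.01, 1.0, allow_nan=False)))
    def test_snv_rows_always_standardised(self, X):
        X = X + np.linspace(0, 1, 16)  # avoid exactly-constant rows
        out = apply_preprocess(PreprocessSpec(PreprocessMethod.SNV), X)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)
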