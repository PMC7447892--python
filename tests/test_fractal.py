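"""Box counting, log-log fits, monofractality, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flocfrac import fractal
from flocfrac.fractal import (BoxCountCurve, aggregate_dimension, bias_correct,
                              box_count, default_ladder, fine_scale_range,
                              fit_fractal_dimension, monofractality_test,
                              normalize_curve, pow2_ladder, sphere_calibration)
from flocfrac.synthetic import menger_sponge, solid_cube, solid_rod

from .oracles import brute_force_box_count

MENGER_D = np.log(20) / np.log(3)


class TestBoxCount:
    def test_filled_cube_counts_are_closed_form(self):
        curve = box_count(solid_cube(64), pow2_ladder(64))
        assert np.array_equal(curve.counts, (64 // curve.sizes.astype(int)) ** 3)

    def test_single_voxel_counts_one_box_at_every_scale(self):
        arr = np.zeros((9, 9, 9), dtype=bool)
        arr[4, 4, 4] = True
        curve = box_count(arr, [1, 2, 3, 9])
        assert np.all(curve.counts == 1)

    def test_menger_sponge_triadic_counts(self):
        curve = box_count(menger_sponge(3), [1, 3, 9, 27])
        assert list(curve.counts) == [8000, 400, 20, 1]

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError, match="empty"):
            box_count(np.zeros((4, 4), dtype=bool))

    def test_oversized_eps_rejected(self):
        with pytest.raises(ValueError):
            box_count(np.ones((4, 4), dtype=bool), [8])

    def test_matches_brute_force_scan(self, rng):
        for _ in range(15):
            shape = tuple(rng.integers(3, 17, size=rng.integers(2, 4)))
            arr = rng.random(shape) < 0.2
            if not arr.any():
                arr.flat[0] = True
            for eps in (1, 2, 3, 5, 7):
                if eps > max(shape):
                    continue
                got = box_count(arr, [eps]).counts[0]
                assert got == brute_force_box_count(arr, eps)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_counts_nonincreasing_and_anchor_n1(self, seed):
        r = np.random.default_rng(seed)
        arr = r.random((12, 12, 12)) < 0.15
        arr[0, 0, 0] = True
        curve = box_count(arr, [1, 2, 3, 4, 6, 12])
        assert curve.counts[0] == arr.sum()
        assert np.all(np.diff(curve.counts) <= 0)


class TestFit:
    @pytest.mark.parametrize("arr,sizes,expected", [
        (solid_cube(64), None, 3.0),
        (np.ones((256, 256), dtype=bool), None, 2.0),
        (solid_rod(256), list(2 ** np.arange(9)), 1.0),
        (menger_sponge(3), [1, 3, 9, 27], MENGER_D),
    ], ids=["cube", "square", "rod", "menger"])
    def test_exact_dimensions(self, arr, sizes, expected):
        curve = box_count(arr, sizes)
        fit = fit_fractal_dimension(curve)
        assert fit.dimension == pytest.approx(expected, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_too_few_points_raises(self):
        curve = BoxCountCurve(sizes=[1, 2], counts=[10, 4], dimensionality=2)
        with pytest.raises(ValueError, match=">= 3"):
            fit_fractal_dimension(curve)

    def test_fit_range_drops_saturated_point(self):
        curve = box_count(solid_cube(16), [1, 2, 4, 8, 16])
        full = fit_fractal_dimension(curve)
        windowed = fit_fractal_dimension(curve, fit_range=(1, 8))
        assert windowed.n_points == 4
        assert windowed.dimension == pytest.approx(full.dimension, abs=1e-9)


class TestMonofractality:
    def test_perfect_line_is_monofractal(self):
        fit = fit_fractal_dimension(box_count(solid_cube(32)))
        assert monofractality_test(fit)

    def test_cube_plus_rod_is_bifractal(self):
        arr = np.zeros((40, 40, 240), dtype=bool)
        arr[:, :, :40] = True                      # solid block: local D = 3
        arr[20, 20, 40:240] = True                 # thin rod: local D = 1
        fit = fit_fractal_dimension(box_count(arr, pow2_ladder(40)))
        assert not fit.monofractal_flag

    def test_two_point_curve_errors_out(self):
        curve = BoxCountCurve(sizes=[1, 4], counts=[64, 4], dimensionality=3)
        with pytest.raises(ValueError):
            fit_fractal_dimension(curve)


class TestSphereCalibration:
    def test_bias_shrinks_with_size(self):
        cal = sphere_calibration([3, 8, 20])
        counts = [c for c, _ in cal]
        dims = [d for _, d in cal]
        assert counts == sorted(counts)
        assert dims == sorted(dims)
        assert dims[-1] > dims[0]

    def test_tiny_sphere_reads_well_below_three(self):
        # radius 1 rasterizes to the 7-voxel cross; triadic ladder since the
        # 3-wide box only supports two power-of-two sizes
        (_, d), = sphere_calibration([1], sizes=[1, 2, 3])
        assert d < 2.0


class TestBiasCorrect:
    CAL = [(100, 2.0), (10000, 2.8)]

    def test_sphere_self_consistency(self):
        cal = sphere_calibration([5, 12, 20])
        for count, d in cal:
            assert bias_correct(d, count, cal) == pytest.approx(3.0, abs=1e-9)

    def test_correction_decreases_with_size(self):
        c_small = bias_correct(2.4, 100, self.CAL) - 2.4
        c_big = bias_correct(2.4, 10000, self.CAL) - 2.4
        assert c_small > c_big

    def test_out_of_range_uses_endpoint_with_warning(self):
        with pytest.warns(UserWarning, match="outside calibration range"):
            d = bias_correct(2.5, 10 ** 6, self.CAL)
        assert d == pytest.approx(2.5 + (3.0 - 2.8))


class TestNormalize:
    def test_slope_invariant_under_rescaling(self):
        curve = box_count(np.ones((64, 64), dtype=bool), pitch_um=0.092)
        norm = normalize_curve(curve, image_length_um=64 * 0.092)
        assert fit_fractal_dimension(norm).dimension == pytest.approx(
            fit_fractal_dimension(curve).dimension, abs=1e-9)
        assert norm.sizes.max() <= 1.0

    def test_two_pitches_share_abscissa(self):
        # same physical object sampled at two resolutions
        fine = box_count(np.ones((128, 128), dtype=bool), pitch_um=0.05)
        coarse = box_count(np.ones((64, 64), dtype=bool), pitch_um=0.1)
        n_fine = normalize_curve(fine, 128 * 0.05)
        n_coarse = normalize_curve(coarse, 64 * 0.1)
        # coarse ladder is a subset of the fine one after normalization
        assert np.allclose(sorted(set(np.round(n_coarse.sizes, 12)) -
                                  set(np.round(n_fine.sizes, 12))), [])


class TestLadders:
    def test_default_ladder_extends_for_flat_arrays(self):
        assert len(default_ladder((1, 1, 256))) == 9  # falls back to max side

    def test_fine_scale_range_keeps_three_points(self):
        lo, hi = fine_scale_range((25, 25, 25))
        sizes = default_ladder((25, 25, 25))
        assert ((sizes >= lo) & (sizes <= hi)).sum() >= 3

    def test_aggregate_dimension_of_solid_block_is_three(self):
        fit = aggregate_dimension(solid_cube(64), feature_size_px=2.0)
        assert fit.dimension == pytest.approx(3.0, abs=1e-9)
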