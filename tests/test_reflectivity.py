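"""Reflectivity formulas, color map rendering, paired t-test."""

import numpy as np
import pytest
from scipy import stats as sstats

from voxreflect import (
    Volume3D,
    invert_color_map,
    normalize_by_water,
    paired_t_test,
    reflectivity_roi,
    reflectivity_voxelwise,
    relative_difference_percent,
    render_color_map,
)


class TestRoiFormula:
    @pytest.mark.parametrize(
        "test_mean,control_mean,expected",
        [(120.0, 100.0, 20.0), (100.0, 100.0, 0.0), (80.0, 100.0, -20.0)],
    )
    def test_direct_formula(self, test_mean, control_mean, expected):
        assert reflectivity_roi(test_mean, control_mean) == pytest.approx(expected)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            reflectivity_roi(10.0, 0.0)

    def test_method_comparison_formula(self):
        assert relative_difference_percent(51.2, 41.2) == pytest.approx(
            (51.2 - 41.2) / 51.2 * 100.0
        )


class TestVoxelwise:
    def _pair(self, tvals, cvals, **kw):
        return (
            Volume3D(np.asarray(tvals, float), (1, 1, 1), **kw),
            Volume3D(np.asarray(cvals, float), (1, 1, 1)),
        )

    def test_identical_volumes_zero_everywhere(self, rng):
        v = rng.uniform(50, 100, (4, 4, 4))
        t, c = self._pair(v, v)
        res = reflectivity_voxelwise(t, c)
        assert res.global_percent == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.voxel_map, 0.0, atol=1e-12)

    def test_uniform_20_percent(self):
        t, c = self._pair(np.full((3, 3, 3), 120.0), np.full((3, 3, 3), 100.0))
        res = reflectivity_voxelwise(t, c)
        assert res.global_percent == pytest.approx(20.0, abs=1e-12)
        np.testing.assert_allclose(res.voxel_map, 20.0, atol=1e-12)
        assert res.n_voxels == 27

    def test_matches_explicit_double_loop(self, rng):
        tv = rng.uniform(50, 150, (4, 4, 4))
        cv = rng.uniform(50, 150, (4, 4, 4))
        t, c = self._pair(tv, cv)
        res = reflectivity_voxelwise(t, c)
        num = den = 0.0
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    num += tv[i, j, k] - cv[i, j, k]
                    den += cv[i, j, k]
        assert res.global_percent == pytest.approx(num / den * 100.0, abs=1e-12)

    def test_global_equals_roi_formula_on_same_mask(self, rng):
        tv = rng.uniform(50, 150, (5, 5, 5))
        cv = rng.uniform(50, 150, (5, 5, 5))
        mask = rng.uniform(size=(5, 5, 5)) > 0.4
        t, c = self._pair(tv, cv)
        res = reflectivity_voxelwise(t, c, mask=mask)
        roi = reflectivity_roi(tv[mask].mean(), cv[mask].mean())
        assert res.global_percent == pytest.approx(roi, rel=1e-9)

    def test_common_scale_invariance(self, rng):
        tv = rng.uniform(50, 150, (4, 4, 4))
        cv = rng.uniform(50, 150, (4, 4, 4))
        r1 = reflectivity_voxelwise(*self._pair(tv, cv)).global_percent
        r2 = reflectivity_voxelwise(*self._pair(7.0 * tv, 7.0 * cv)).global_percent
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_shared_water_reference_normalization_invariance(self, rng):
        tv = rng.uniform(50, 150, (6, 6, 6))
        cv = rng.uniform(50, 150, (6, 6, 6))
        water = np.zeros((6, 6, 6), bool)
        water[0] = True
        tv[water] = cv[water]  # both scans see the same water tube signal
        t, c = self._pair(tv, cv)
        r_raw = reflectivity_voxelwise(t, c, mask=~water).global_percent
        tn = normalize_by_water(t, water)
        cn = normalize_by_water(c, water)
        r_norm = reflectivity_voxelwise(tn, cn, mask=~water).global_percent
        assert r_norm == pytest.approx(r_raw, rel=1e-9)

    def test_invalid_and_nonpositive_control_excluded(self, rng):
        tv = rng.uniform(50, 150, (3, 3, 3))
        cv = rng.uniform(50, 150, (3, 3, 3))
        cv[0, 0, 0] = -5.0
        valid = np.ones((3, 3, 3), bool)
        valid[1, 1, 1] = False
        t = Volume3D(tv, (1, 1, 1), valid=valid)
        c = Volume3D(cv, (1, 1, 1))
        res = reflectivity_voxelwise(t, c)
        assert res.n_voxels == 25
        assert np.isnan(res.voxel_map[0, 0, 0]) and np.isnan(res.voxel_map[1, 1, 1])

    def test_mismatched_grids_rejected(self, rng):
        t = Volume3D(rng.normal(size=(3, 3, 3)), (1, 1, 1))
        c = Volume3D(rng.normal(size=(4, 4, 4)), (1, 1, 1))
        with pytest.raises(ValueError, match="grid"):
            reflectivity_voxelwise(t, c)
        c2 = Volume3D(rng.normal(size=(3, 3, 3)), (2, 2, 2))
        with pytest.raises(ValueError, match="grid"):
            reflectivity_voxelwise(t, c2)

    def test_nonpositive_control_sum_rejected(self):
        t = Volume3D(np.ones((2, 2, 2)), (1, 1, 1))
        c = Volume3D(np.full((2, 2, 2), -1.0), (1, 1, 1))
        with pytest.raises(ValueError):
            reflectivity_voxelwise(t, c)


class TestColorMap:
    def _result(self, vm):
        from voxreflect.reflectivity import ReflectivityResult

        vm = np.asarray(vm, dtype=float)
        return ReflectivityResult(0.0, vm, int(np.isfinite(vm).sum()))

    def test_zero_map_symmetric_range_is_midpoint_color(self):
        rgba, legend = render_color_map(self._result(np.zeros((3, 3, 2))), (-50, 50))
        mid = legend["lut"][128]
        assert np.allclose(rgba, mid)

    def test_endpoints_map_to_endpoint_colors(self):
        vm = np.array([[[-100.0, 100.0]]])
        rgba, legend = render_color_map(self._result(vm), (-100, 100))
        np.testing.assert_allclose(rgba[0, 0, 0], legend["lut"][0])
        np.testing.assert_allclose(rgba[0, 0, 1], legend["lut"][255])

    def test_out_of_range_clipped_to_endpoints(self):
        vm = np.array([[[-500.0, 500.0]]])
        rgba, legend = render_color_map(self._result(vm), (-100, 100))
        np.testing.assert_allclose(rgba[0, 0, 0], legend["lut"][0])
        np.testing.assert_allclose(rgba[0, 0, 1], legend["lut"][255])

    def test_flagged_voxels_transparent(self):
        vm = np.full((2, 2, 2), np.nan)
        vm[0, 0, 0] = 10.0
        rgba, _ = render_color_map(self._result(vm))
        assert rgba[0, 0, 0, 3] == 1.0
        assert np.all(rgba[..., 3].ravel()[1:] == 0.0)

    def test_roundtrip_within_one_quantization_step(self, rng):
        vm = rng.uniform(-90, 90, (4, 4, 3))
        res = self._result(vm)
        rgba, legend = render_color_map(res, (-100, 100))
        back = invert_color_map(rgba, legend)
        step = (legend["hi"] - legend["lo"]) / 255.0
        assert np.nanmax(np.abs(back - vm)) <= step + 1e-9

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            render_color_map(self._result(np.zeros((2, 2, 2))), (10, 10))


class TestPairedTTest:
    def test_identical_samples_convention(self):
        res = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.p_two_tailed == 1.0
        assert res.degrees_of_freedom == 2

    def test_hand_formula_on_differences_1_2_3(self):
        res = paired_t_test([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)), abs=1e-9)
        assert res.t_statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.degrees_of_freedom == 2
        # independent t-distribution oracle for the two-tailed p
        assert res.p_two_tailed == pytest.approx(
            2.0 * (1.0 - sstats.t.cdf(res.t_statistic, 2)), abs=1e-12
        )

    def test_matches_scipy_paired_oracle(self, rng):
        x = rng.normal(10, 2, 8)
        y = rng.normal(9, 2, 8)
        res = paired_t_test(x, y)
        oracle = sstats.ttest_rel(x, y)
        assert res.t_statistic == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p_two_tailed == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_swapping_inputs_negates_t_preserves_p(self, rng):
        x = rng.normal(10, 2, 6)
        y = rng.normal(9, 2, 6)
        a = paired_t_test(x, y)
        b = paired_t_test(y, x)
        assert b.t_statistic == pytest.approx(-a.t_statistic, abs=1e-12)
        assert b.p_two_tailed == pytest.approx(a.p_two_tailed, abs=1e-12)

    def test_zero_variance_nonzero_differences_limit(self):
        res = paired_t_test([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert np.isinf(res.t_statistic) and res.t_statistic > 0
        assert res.p_two_tailed == 0.0

    def test_too_short_or_mismatched_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0], [2.0])
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0, 2.0, 3.0])
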