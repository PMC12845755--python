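"""Macro-scale porosity summaries, profiles, and treatment statistics."""

import numpy as np
import pandas as pd
import pytest

from pomoct.calibration import PorosityVolume
from pomoct.porosity import (compare_groups, line_profile,
                             macro_micro_correlation, regional_summary,
                             slice_porosity_map, whole_fruit_porosity)
from pomoct.segmentation import REGION_CODES, FruitMasks

SPACING = (0.5, 0.339, 0.339)


def _uniform_fruit(value=25.0, shape=(10, 12, 12)):
    pmap = PorosityVolume(np.full(shape, value), SPACING)
    labels = np.ones(shape, dtype=np.int32)
    masks = FruitMasks(labels, SPACING, {1: int(np.prod(shape))},
                       {1: (0.0, 0.0, 0.0)})
    return pmap, masks


class TestWholeFruitMean:
    def test_uniform_phantom_mean_is_exact(self):
        pmap, masks = _uniform_fruit(25.0)
        assert whole_fruit_porosity(pmap, masks) == {1: 25.0}

    def test_mean_conserves_regional_decomposition(self, small_fruit,
                                                   small_fruit_pipeline):
        _, pmap, masks, regions = small_fruit_pipeline
        whole = whole_fruit_porosity(pmap, masks)[1]
        summary = regional_summary(pmap, regions, masks)
        weighted = float(np.nansum(summary.mean_porosity_pct
                                   * summary.voxel_count)
                         / summary.voxel_count.sum())
        assert whole == pytest.approx(weighted, rel=1e-9)

    def test_excluding_cavity_matches_closed_form_mixture(self, small_fruit,
                                                          small_fruit_pipeline):
        _, pmap, masks, _ = small_fruit_pipeline
        truth_regions = small_fruit.regions
        with_cavity = whole_fruit_porosity(pmap, masks)[1]
        without = whole_fruit_porosity(pmap, masks, include_cavity=False,
                                       regions=truth_regions)[1]
        n = masks.voxel_counts[1]
        n_cav = int(np.sum(truth_regions.regions == REGION_CODES["cavity"]))
        cav_mean = float(pmap.porosity[truth_regions.regions
                                       == REGION_CODES["cavity"]].mean())
        expected = (with_cavity * n - cav_mean * n_cav) / (n - n_cav)
        assert without == pytest.approx(expected, rel=1e-9)

    def test_empty_mask_rejected(self):
        pmap, _ = _uniform_fruit()
        empty = FruitMasks(np.zeros(pmap.shape, np.int32), SPACING,
                           {1: 0}, {1: (0, 0, 0)})
        with pytest.raises(ValueError, match="no fruit voxels"):
            whole_fruit_porosity(pmap, empty)


class TestLineProfile:
    def test_constant_region_gives_flat_profile(self):
        pmap, _ = _uniform_fruit(25.0)
        df = line_profile(pmap, (0.5, 0.4, 0.4), (4.0, 3.0, 3.0), 50)
        assert np.allclose(df.porosity_pct, 25.0)
        assert df.position_mm.iloc[0] == 0.0

    def test_two_samples_are_the_endpoints(self):
        arr = np.zeros((4, 4, 4))
        arr[0, 0, 0], arr[3, 3, 3] = 10.0, 90.0
        pmap = PorosityVolume(arr, (1.0, 1.0, 1.0))
        df = line_profile(pmap, (0, 0, 0), (3.0, 3.0, 3.0), 2)
        assert list(df.porosity_pct) == [10.0, 90.0]

    def test_profile_peaks_at_cavity_crossing(self, small_fruit):
        # diameter profile through a cavity lobe: gas shows as local max
        pmap = small_fruit.porosity
        regions = small_fruit.regions.regions
        idx = np.argwhere(regions == REGION_CODES["cavity"])
        mid = idx[len(idx) // 2]
        spacing = np.asarray(pmap.spacing_mm)
        p0 = mid * spacing - [0, 0, 3.0]
        p1 = mid * spacing + [0, 0, 3.0]
        df = line_profile(pmap, tuple(p0), tuple(p1), 101)
        assert df.porosity_pct.max() == pytest.approx(100.0, abs=1.0)
        assert 40 <= int(df.porosity_pct.idxmax()) <= 60

    def test_translation_by_whole_voxels_is_exact(self, rng):
        arr = rng.uniform(0, 100, (6, 6, 6))
        pmap = PorosityVolume(arr, (1.0, 1.0, 1.0))
        shifted = PorosityVolume(np.pad(arr, ((2, 0), (0, 2), (0, 2)),
                                        mode="edge"), (1.0, 1.0, 1.0))
        a = line_profile(pmap, (0.2, 0.5, 0.5), (4.5, 4.0, 4.0), 33)
        b = line_profile(shifted, (2.2, 0.5, 0.5), (6.5, 4.0, 4.0), 33)
        assert np.allclose(a.porosity_pct, b.porosity_pct)

    def test_out_of_bounds_endpoint_rejected(self):
        pmap, _ = _uniform_fruit()
        with pytest.raises(ValueError, match="outside volume"):
            line_profile(pmap, (0, 0, 0), (999.0, 0, 0), 10)


class TestSliceMap:
    def test_plane_equals_direct_indexing(self, small_fruit):
        pmap = small_fruit.porosity
        plane, in_plane = slice_porosity_map(pmap, "row", 20)
        np.testing.assert_array_equal(plane, pmap.porosity[:, 20, :])
        assert in_plane == (pmap.spacing_mm[0], pmap.spacing_mm[2])

    def test_central_slice_shows_sub_ten_percent_seeds(self, small_fruit):
        mid = small_fruit.porosity.shape[0] // 2
        plane, _ = slice_porosity_map(small_fruit.porosity, "slice", mid)
        seeds = small_fruit.regions.regions[mid] == REGION_CODES["seed"]
        assert seeds.any() and np.all(plane[seeds] < 10.0)

    def test_index_out_of_range(self, small_fruit):
        with pytest.raises(IndexError):
            slice_porosity_map(small_fruit.porosity, "slice", 10_000)


class TestGroupComparison:
    def test_identical_groups_give_zero_f(self):
        df = pd.DataFrame({"value": [1.0, 2, 3, 1, 2, 3],
                           "group": list("aaabbb")})
        res = compare_groups(df)
        assert res.f_statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_crop_load_sized_effects_are_detected(self, rng):
        means = {"high": 24.70, "standard": 26.44, "low": 29.06}
        rows = [{"value": rng.normal(m, 0.5), "group": g}
                for g, m in means.items() for _ in range(9)]
        res = compare_groups(pd.DataFrame(rows))
        assert res.p_value < 0.001
        assert np.all(res.tukey.p_adj < 0.05)

    def test_null_type_one_error_near_nominal(self, rng):
        hits = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"value": rng.normal(0, 1, 27),
                               "group": np.repeat(list("abc"), 9)})
            hits += compare_groups(df).p_value < 0.05
        assert 0.01 < hits / reps < 0.10

    def test_insufficient_replication_rejected(self):
        df = pd.DataFrame({"value": [1.0, 2, 3], "group": ["a", "a", "b"]})
        with pytest.raises(ValueError, match="insufficient replication"):
            compare_groups(df)


class TestMacroMicroCorrelation:
    def test_identical_vectors_give_unit_correlation(self):
        x = np.arange(10.0)
        res = macro_micro_correlation(x, x)
        assert res["pearson_r"] == pytest.approx(1.0)
        assert res["spearman_r"] == pytest.approx(1.0)

    def test_antimonotone_pair_gives_minus_one_rank(self):
        x = np.arange(8.0)
        res = macro_micro_correlation(x, np.exp(-x))
        assert res["spearman_r"] == pytest.approx(-1.0)

    def test_constant_vector_flags_undefined(self):
        res = macro_micro_correlation(np.ones(5), np.arange(5.0))
        assert np.isnan(res["pearson_r"]) and np.isnan(res["spearman_r"])

    def test_estimate_within_fisher_interval_at_known_r(self, rng):
        # r = 0.7, n = 18 mirrors the macro-micro sample size
        n, rho = 18, 0.7
        cov = [[1, rho], [rho, 1]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        r = macro_micro_correlation(xy[:, 0], xy[:, 1])["pearson_r"]
        z, se = np.arctanh(r), 1 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - 1.96 * se), np.tanh(z + 1.96 * se)
        assert lo < rho < hi
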