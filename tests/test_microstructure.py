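"""High-resolution ROI analysis: enhancement, blob detection, morphometrics."""

import numpy as np
import pytest

from pomoct.microstructure import (Blob, compute_metrics, detect_blobs,
                                   enhance_contrast, extract_roi,
                                   measure_roi_porosity, paired_position_test)
from pomoct.phantoms import CellPhantomSpec, make_cell_phantom
from pomoct.volume_io import GreyVolume

VOXEL_MM = 6.6e-3
SPACING = (VOXEL_MM,) * 3


def _paint_spheres(shape, centers_vox, radii_vox, fg=1000, bg=-500):
    arr = np.full(shape, bg, dtype=np.int16)
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij",
                        sparse=True)
    for c, r in zip(centers_vox, radii_vox):
        inside = sum((g - ci) ** 2 for g, ci in zip(grids, c)) <= r ** 2
        arr[inside] = fg
    return GreyVolume(arr, SPACING)


class TestExtractRoi:
    def test_half_millimetre_cube_spans_76_voxels(self):
        vol = GreyVolume(np.zeros((120, 120, 120), np.int16), SPACING)
        center = tuple(60 * VOXEL_MM for _ in range(3))
        roi = extract_roi(vol, center, edge_mm=0.5)
        assert roi.shape == (76, 76, 76)
        assert roi.spacing_mm == SPACING

    def test_uniform_volume_gives_uniform_roi(self):
        vol = GreyVolume(np.full((90, 90, 90), 7, np.int16), SPACING)
        roi = extract_roi(vol, (0.3, 0.3, 0.3), 0.5)
        assert np.all(roi.voxels == 7)

    def test_roi_clipped_by_boundary_rejected(self):
        vol = GreyVolume(np.zeros((40, 40, 40), np.int16), SPACING)
        with pytest.raises(ValueError, match="out of bounds"):
            extract_roi(vol, (0.02, 0.02, 0.02), 0.5)


class TestEnhanceContrast:
    def test_two_valued_roi_maps_onto_unit_endpoints(self):
        vol = _paint_spheres((30, 30, 30), [(15, 15, 15)], [6])
        enh = enhance_contrast(vol)
        assert set(np.unique(enh)) == {0.0, 1.0}

    def test_output_stays_in_unit_interval(self, rng):
        vol = GreyVolume(rng.integers(-2000, 2000, (20, 20, 20)).astype(np.int16),
                         SPACING)
        for method in ("percentile_stretch", "adaptive_equalize"):
            enh = enhance_contrast(vol, method=method)
            assert enh.min() >= 0.0 and enh.max() <= 1.0

    def test_constant_roi_rejected(self):
        vol = GreyVolume(np.full((8, 8, 8), 3, np.int16), SPACING)
        with pytest.raises(ValueError, match="no contrast"):
            enhance_contrast(vol)

    def test_stretch_preserves_phase_assignment(self, cell_phantom):
        from pomoct.microstructure import _phase_thresholds
        raw = cell_phantom.grey.voxels.astype(np.float64)
        enh = enhance_contrast(cell_phantom.grey)
        lo_r, hi_r = _phase_thresholds(raw)
        lo_e, hi_e = _phase_thresholds(enh)
        classes_raw = np.digitize(raw, [lo_r, hi_r])
        classes_enh = np.digitize(enh, [lo_e, hi_e])
        assert np.mean(classes_raw == classes_enh) >= 0.99


class TestDetectBlobs:
    def test_fifty_isolated_spheres_counted_exactly(self):
        phantom = make_cell_phantom(CellPhantomSpec(
            seed=21, n_cells=50, pore_volume_ratio=0.0, noise_sd=0.0))
        enh = enhance_contrast(phantom.grey)
        blobs = detect_blobs(enh, "bright", SPACING,
                             diameter_range_um=(30, 150))
        assert len(blobs) == 50
        truth = phantom.truth.sort_values(
            ["center_slice_mm", "center_row_mm", "center_col_mm"])
        found = sorted(blobs, key=lambda b: b.center_mm)
        for b, (_, t) in zip(found, truth.iterrows()):
            assert abs(b.equivalent_diameter_um - t.diameter_um) <= 2 * 6.6

    def test_touching_pair_split_by_watershed(self):
        r = 6
        vol = _paint_spheres((40, 40, 40), [(20, 20, 14), (20, 20, 14 + int(1.8 * r))], [r, r])
        enh = enhance_contrast(vol)
        blobs = detect_blobs(enh, "bright", SPACING, diameter_range_um=(40, 120))
        assert len(blobs) == 2

    def test_bright_query_on_all_dark_roi_is_empty(self):
        vol = _paint_spheres((20, 20, 20), [(10, 10, 10)], [4],
                             fg=-500, bg=-500 )
        arr = vol.voxels.copy()
        arr[0, 0, 0] = -499  # minimal contrast so thresholding is defined
        enh = enhance_contrast(GreyVolume(arr, SPACING))
        assert detect_blobs(enh, "bright", SPACING,
                            diameter_range_um=(30, 100)) == []

    @pytest.mark.parametrize("r_vox", [3, 5, 8])
    def test_equivalent_diameter_matches_analytic_sphere(self, r_vox):
        vol = _paint_spheres((40, 40, 40), [(20, 20, 20)], [r_vox])
        enh = enhance_contrast(vol)
        blobs = detect_blobs(enh, "bright", SPACING, diameter_range_um=(10, 200))
        assert len(blobs) == 1
        expected = 2 * r_vox * 6.6
        assert abs(blobs[0].equivalent_diameter_um - expected) <= 6.6


class TestComputeMetrics:
    @staticmethod
    def _blob(d_um, vox, boundary=False, polarity="bright"):
        return Blob((0, 0, 0), d_um, vox, polarity, boundary)

    def test_interior_count_reproduces_published_density(self):
        cells = [self._blob(69.0, 500) for _ in range(200)]
        m = compute_metrics(cells, [], roi_volume_mm3=0.125,
                            voxel_volume_mm3=VOXEL_MM ** 3)
        assert m.cell_density_per_mm3 == pytest.approx(1600.0)
        assert m.cell_density_per_mm3 == pytest.approx(m.cell_count / 0.125)

    def test_boundary_cells_count_half(self):
        cells = [self._blob(69.0, 500)] * 10 + \
                [self._blob(69.0, 500, boundary=True)] * 4
        m = compute_metrics(cells, [], 0.125, VOXEL_MM ** 3)
        assert m.cell_count == 12.0
        assert m.n_cells_boundary == 4

    def test_pore_ratio_is_voxel_fraction(self):
        vol_mm3 = 1000 * VOXEL_MM ** 3
        pores = [self._blob(20.0, 27, polarity="dark")]
        m = compute_metrics([], pores, vol_mm3, VOXEL_MM ** 3)
        assert m.pore_volume_ratio == pytest.approx(0.027)
        assert m.roi_porosity_pct == pytest.approx(2.7)

    def test_no_pores_flags_undefined_diameter(self):
        m = compute_metrics([self._blob(69.0, 500)], [], 0.125, VOXEL_MM ** 3)
        assert m.pore_volume_ratio == 0.0
        assert np.isnan(m.mean_pore_diameter_um)

    def test_pore_volume_never_exceeds_roi(self, cell_phantom, cell_detection):
        _, _, pores = cell_detection
        total = sum(b.voxel_count for b in pores) * cell_phantom.grey.voxel_volume_mm3
        roi = float(np.prod(cell_phantom.grey.shape)) * cell_phantom.grey.voxel_volume_mm3
        assert total <= roi


class TestPhantomRecovery:
    def test_mean_cell_diameter_within_three_percent(self, cell_phantom,
                                                     cell_detection):
        _, cells, _ = cell_detection
        m = compute_metrics(cells, [], 0.126, cell_phantom.grey.voxel_volume_mm3)
        truth = cell_phantom.truth.query("polarity == 'bright'").diameter_um.mean()
        assert m.mean_cell_diameter_um == pytest.approx(truth, rel=0.03)

    def test_gas_fraction_recovered_by_thresholding(self, cell_phantom):
        enh = enhance_contrast(cell_phantom.grey)
        measured = measure_roi_porosity(enh)
        assert measured == pytest.approx(
            100 * cell_phantom.achieved_pore_volume_ratio, abs=0.5)


class TestPairedPositionTest:
    @staticmethod
    def _metrics(porosity, roi_id="r", pos=""):
        from pomoct.microstructure import MicrostructureMetrics
        return MicrostructureMetrics(roi_id, pos, 69.0, 200, 200, 0, 1600.0,
                                     30.0, 50, porosity / 100, porosity)

    def test_identical_arms_give_zero_difference(self):
        sunny = [self._metrics(15.0), self._metrics(16.0)]
        shady = [self._metrics(15.0), self._metrics(16.0)]
        table = paired_position_test(sunny, shady, ["a", "b"])
        row = table.set_index("metric").loc["roi_porosity_pct"]
        assert row.mean_difference == 0.0 and row.p_value == 1.0

    def test_constant_nonzero_difference_flags_undefined_p(self):
        sunny = [self._metrics(16.0), self._metrics(17.0)]
        shady = [self._metrics(15.0), self._metrics(16.0)]
        table = paired_position_test(sunny, shady, ["a", "b"])
        row = table.set_index("metric").loc["roi_porosity_pct"]
        assert row.mean_difference == pytest.approx(1.0)
        assert np.isnan(row.p_value)

    def test_unpaired_apple_rejected(self):
        with pytest.raises(ValueError, match="incomplete pair"):
            paired_position_test([self._metrics(15.0)],
                                 [self._metrics(15.0), self._metrics(16.0)],
                                 ["a", "b"])

    def test_planted_offset_recovered_from_phantom_pairs(self):
        from pomoct.studies import run_paired_position_study
        study = run_paired_position_study(
            edge_mm=0.2, cell_diameter_um=40.0, packing_fraction=0.18,
            use_blobs=False, seed=77)
        assert study.recovered_offset_pct == pytest.approx(1.71, abs=0.5)
        assert study.porosity_p_value < 0.05
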