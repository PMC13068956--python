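"""Monolayer image quantifications: density, height, shape, ratios, events."""

import numpy as np
import pytest
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from epimech import monolayer as ml
from epimech import synthetic as syn


class TestNucleiDensity:
    def test_recovers_truth_count_and_density(self, monolayer_field):
        channels, _, _, truth = monolayer_field
        density, count, _ = ml.count_nuclei_density(channels["nuclei"])
        assert abs(count - truth["n_cells"]) / truth["n_cells"] <= 0.02
        assert density == pytest.approx(truth["density_cells_per_mm2"],
                                        rel=0.02)

    def test_blank_image_gives_zero_with_warning(self):
        blank = ml.IntensityImage(np.zeros((50, 50)), 1.0)
        with pytest.warns(UserWarning):
            density, count, _ = ml.count_nuclei_density(blank)
        assert density == 0.0 and count == 0

    def test_touching_nuclei_split_by_watershed(self):
        img = np.zeros((60, 60))
        for center in ((30, 24), (30, 33)):  # two overlapping r=6 disks
            rr, cc = draw_disk(center, 6)
            img[rr, cc] = 200.0
        _, count, _ = ml.count_nuclei_density(
            ml.IntensityImage(img, 1.0), min_separation_px=5)
        assert count == 2

    def test_density_linear_in_cell_count(self):
        ch1, _, _, t1 = syn.gen_monolayer_images(
            density_cells_per_mm2=1000, seed=2)
        ch2, _, _, t2 = syn.gen_monolayer_images(
            density_cells_per_mm2=2000, seed=2)
        d1, _, _ = ml.count_nuclei_density(ch1["nuclei"])
        d2, _, _ = ml.count_nuclei_density(ch2["nuclei"])
        assert d2 / d1 == pytest.approx(t2["n_cells"] / t1["n_cells"],
                                        rel=0.02)


class TestProliferationFraction:
    def test_count_arithmetic(self):
        assert ml.proliferation_fraction(2, 1000) == pytest.approx(0.2)
        assert ml.proliferation_fraction(0, 500) == 0.0

    def test_mask_input_counts_components(self):
        ch, _, _, t = syn.gen_monolayer_images(positive_fraction=0.003, seed=9)
        frac = ml.proliferation_fraction(ch["positive"], t["n_cells"])
        assert frac == pytest.approx(t["positive_fraction_percent"])

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            ml.proliferation_fraction(1, 0)


class TestCellHeight:
    @pytest.mark.parametrize("thickness_um", [9.1, 11.6])
    def test_uniform_slab_measured_exactly(self, thickness_um):
        axial = 0.1
        n_rows = int(round(thickness_um / axial))
        mask = np.zeros((200, 120), bool)
        mask[40:40 + n_rows] = True
        section = ml.CrossSectionMask(mask, 1.0, axial)
        heights, mean = ml.measure_cell_height(section, n_positions=10)
        assert mean == pytest.approx(thickness_um, abs=1e-9)
        assert np.all(heights == heights[0])  # isotropy across positions

    def test_single_pixel_sheet(self):
        mask = np.zeros((10, 30), bool)
        mask[5] = True
        _, mean = ml.measure_cell_height(
            ml.CrossSectionMask(mask, 1.0, 0.5), n_positions=3)
        assert mean == pytest.approx(0.5)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ml.measure_cell_height(
                ml.CrossSectionMask(np.zeros((5, 5), bool), 1.0, 1.0))


class TestShapeFactor:
    def test_square_approaches_four(self):
        labels = np.zeros((120, 120), int)
        labels[10:110, 10:110] = 1
        q = ml.shape_factor(ml.CellLabelMap(labels, 1.0))["shape_factor"][0]
        assert q == pytest.approx(4.0, rel=0.01)

    def test_circle_approaches_isoperimetric_minimum(self):
        labels = np.zeros((140, 140), int)
        rr, cc = draw_disk((70, 70), 55)
        labels[rr, cc] = 1
        q = ml.shape_factor(ml.CellLabelMap(labels, 1.0))["shape_factor"][0]
        assert q == pytest.approx(2 * np.sqrt(np.pi), rel=0.02)

    def test_scale_invariance(self):
        small = np.zeros((60, 60), int)
        small[20:40, 15:45] = 1
        big = np.kron(small, np.ones((2, 2), int))
        q_small = ml.shape_factor(ml.CellLabelMap(small, 1.0))["shape_factor"][0]
        q_big = ml.shape_factor(ml.CellLabelMap(big, 1.0))["shape_factor"][0]
        assert q_big == pytest.approx(q_small, rel=0.02)

    def test_isoperimetric_lower_bound_on_voronoi_cells(self, monolayer_field):
        _, cells, _, _ = monolayer_field
        table = ml.shape_factor(cells)
        assert len(table) > 100
        assert (table["shape_factor"] >= 2 * np.sqrt(np.pi) - 0.05).all()

    def test_border_cells_excluded(self):
        labels = np.zeros((50, 50), int)
        labels[0:20, 0:20] = 1   # touches the border
        labels[25:40, 25:40] = 2
        table = ml.shape_factor(ml.CellLabelMap(labels, 1.0))
        assert table["cell_id"].tolist() == [2]

    def test_shape_index_identity(self):
        assert ml.shape_index(4.0, 1.0) == 4.0


class TestStressFibreFraction:
    def test_count_arithmetic(self):
        labels = np.arange(1, 101).reshape(10, 10).repeat(5, 0).repeat(5, 1)
        out = ml.stress_fibre_fraction(10, ml.CellLabelMap(labels, 1.0))
        assert out["percent"] == pytest.approx(10.0)

    def test_zero_flags(self):
        labels = np.ones((10, 10), int)
        assert ml.stress_fibre_fraction(0, ml.CellLabelMap(labels, 1.0)
                                        )["percent"] == 0.0

    def test_background_points_bookkept_separately(self):
        labels = np.zeros((20, 20), int)
        labels[5:15, 5:15] = 1
        pts = [(10.0, 10.0), (1.0, 1.0)]  # one on the cell, one on background
        out = ml.stress_fibre_fraction(pts, ml.CellLabelMap(labels, 1.0))
        assert out["n_flagged"] == 1
        assert out["n_background_flags"] == 1

    def test_more_flags_than_cells_rejected(self):
        labels = np.ones((10, 10), int)
        with pytest.raises(ValueError):
            ml.stress_fibre_fraction(5, ml.CellLabelMap(labels, 1.0))


class TestMicrovilliLength:
    def _band(self, minor_px, rotation=0.0):
        img = np.zeros((200, 200))
        rr, cc = draw_ellipse(100, 100, minor_px / 2, 60,
                              rotation=rotation, shape=img.shape)
        img[rr, cc] = 255.0
        return img

    def test_known_minor_axis_recovered(self):
        # minor axis 1.0 µm at 0.05 µm/px → 20 px
        img = ml.IntensityImage(self._band(20), 0.05)
        lengths = ml.microvilli_length(img, gaussian_sigma=1.0)
        assert lengths.size == 1
        assert lengths[0] == pytest.approx(1.0, rel=0.05)

    def test_rotation_invariance(self):
        a = ml.microvilli_length(
            ml.IntensityImage(self._band(20), 0.05), gaussian_sigma=1.0)[0]
        b = ml.microvilli_length(
            ml.IntensityImage(self._band(20, rotation=np.pi / 4), 0.05),
            gaussian_sigma=1.0)[0]
        assert b == pytest.approx(a, rel=0.05)

    def test_circle_minor_axis_is_diameter(self):
        img = np.zeros((100, 100))
        rr, cc = draw_disk((50, 50), 15)
        img[rr, cc] = 255.0
        lengths = ml.microvilli_length(ml.IntensityImage(img, 1.0),
                                       gaussian_sigma=0.5)
        assert lengths[0] == pytest.approx(30.0, rel=0.05)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ml.microvilli_length(ml.IntensityImage(np.zeros((50, 50)), 1.0),
                                 threshold_method=10.0)


class TestIntensityRatios:
    def test_junctional_cytoplasmic_truth_recovery(self, monolayer_field):
        channels, cells, _, truth = monolayer_field
        out = ml.junctional_cytoplasmic_ratio(channels["junction"], cells)
        assert out["ratio"] == pytest.approx(
            truth["junctional_cytoplasmic_ratio"], rel=1e-9)

    def test_uniform_image_gives_unit_ratio(self, monolayer_field):
        _, cells, _, _ = monolayer_field
        uniform = ml.IntensityImage(np.full(cells.labels.shape, 80.0), 1.0)
        assert ml.junctional_cytoplasmic_ratio(uniform, cells)["ratio"] == 1.0

    def test_constant_offset_pulls_ratio_toward_one(self, monolayer_field):
        channels, cells, _, _ = monolayer_field
        shifted = ml.IntensityImage(channels["junction"].pixels + 100.0, 1.0)
        r0 = ml.junctional_cytoplasmic_ratio(channels["junction"], cells)["ratio"]
        r1 = ml.junctional_cytoplasmic_ratio(shifted, cells)["ratio"]
        assert 1.0 < r1 < r0

    def test_nuclear_cytoplasmic_truth_recovery(self, monolayer_field):
        channels, _, nuclei, truth = monolayer_field
        out = ml.nuclear_cytoplasmic_ratio(channels["nuclear_factor"], nuclei)
        assert out["ratio"] == pytest.approx(
            truth["nuclear_cytoplasmic_ratio"], rel=1e-9)

    def test_equal_intensities_give_unit_ratio(self, monolayer_field):
        _, _, nuclei, _ = monolayer_field
        uniform = ml.IntensityImage(np.full(nuclei.labels.shape, 120.0), 1.0)
        assert ml.nuclear_cytoplasmic_ratio(uniform, nuclei)["ratio"] == 1.0


class TestThresholdedJunctionalMean:
    def test_only_supra_threshold_pixels_enter(self):
        img = np.zeros((100, 100))
        img[:10] = 200.0  # 10% bright junctional signal
        out = ml.thresholded_junctional_mean(
            ml.IntensityImage(img, 1.0), threshold_method=100.0)
        assert out == 200.0

    def test_uniform_above_threshold(self):
        img = ml.IntensityImage(np.full((20, 20), 180.0), 1.0)
        assert ml.thresholded_junctional_mean(img, threshold_method=50.0) == 180.0

    def test_generated_junction_intensity_recovered(self, monolayer_field):
        channels, _, _, truth = monolayer_field
        out = ml.thresholded_junctional_mean(channels["junction"])
        assert out == pytest.approx(truth["intensities"]["junction"], rel=0.01)

    def test_empty_region_rejected(self):
        img = ml.IntensityImage(np.full((20, 20), 10.0), 1.0)
        with pytest.raises(ValueError):
            ml.thresholded_junctional_mean(img, threshold_method=50.0)


class TestCountExtrusions:
    def test_truth_events_counted_exactly(self, extrusion_movie_2pct):
        movie, truth = extrusion_movie_2pct
        count, percent = ml.count_extrusions(movie, n_cells=500)
        assert count == truth["n_events"] == 10
        assert percent == pytest.approx(2.0)

    def test_no_events_counted_as_zero(self):
        movie, _ = syn.gen_extrusion_movie(extrusion_fraction=0.0, seed=1)
        count, percent = ml.count_extrusions(movie, n_cells=500)
        assert count == 0 and percent == 0.0

    def test_stage_drift_corrected_by_alignment(self):
        movie, truth = syn.gen_extrusion_movie(drift_px_per_frame=(2, 1),
                                               seed=3)
        count, _ = ml.count_extrusions(movie, n_cells=500, align=True)
        assert count == truth["n_events"]

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError):
            ml.count_extrusions(np.zeros((1, 20, 20)), n_cells=10)
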