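"""Apical surface, 3D particle segmentation, classification and area."""

import numpy as np
import pandas as pd
import pytest

from epimech import pos
from epimech import synthetic as syn


def _stack_from_actin(actin, voxel=(0.1, 0.5, 0.5)):
    return pos.Stack3D({"actin": actin,
                        "pos": np.zeros_like(actin)}, voxel)


class TestApicalSurface:
    def test_flat_slab_cutoff(self, pos_stack_30_20):
        stack, truth = pos_stack_30_20
        surface = pos.build_apical_surface(stack)
        assert surface.cutoff_um == pytest.approx(truth["cutoff_um"], abs=1e-9)

    def test_tilted_plane_cutoff_is_mean(self):
        # column tops ramp linearly from 8 to 10 µm → mean height 9 µm
        dz = 0.1
        nz, ny, nx = 120, 4, 21
        actin = np.zeros((nz, ny, nx), np.float32)
        tops_um = np.linspace(8.0, 10.0, nx)
        for x, h in enumerate(tops_um):
            top = int(round(h / dz)) - 1
            actin[max(top - 5, 0):top + 1, :, x] = 200.0
        surface = pos.build_apical_surface(_stack_from_actin(actin))
        assert surface.cutoff_um == pytest.approx(9.0, abs=dz / 2)

    def test_empty_channel_rejected(self):
        with pytest.raises(ValueError):
            pos.build_apical_surface(
                _stack_from_actin(np.zeros((10, 5, 5), np.float32)))

    def test_mostly_missing_columns_rejected(self):
        actin = np.zeros((20, 10, 10), np.float32)
        actin[10, 0, 0] = 200.0  # a single column with signal
        with pytest.raises(ValueError, match="unreliable"):
            pos.build_apical_surface(_stack_from_actin(actin),
                                     threshold_method=100.0)


class TestSegmentParticles:
    def test_all_truth_particles_found(self, pos_stack_30_20):
        stack, truth = pos_stack_30_20
        particles = pos.segment_particles(stack)
        assert len(particles) == len(truth["particles"]) == 50

    def test_volume_is_voxel_count_times_voxel_volume(self):
        grid = np.zeros((20, 20, 20), np.float32)
        grid[5:7, 5:7, 5:7] = 150.0  # 8 voxels
        stack = pos.Stack3D({"actin": np.zeros_like(grid), "pos": grid},
                            (0.5, 0.4, 0.25))  # voxel volume 0.05 µm³
        particles = pos.segment_particles(stack, threshold_method=75.0)
        assert len(particles) == 1
        assert particles["volume_um3"][0] == pytest.approx(0.4)

    def test_speckle_below_min_voxels_removed(self):
        grid = np.zeros((20, 20, 20), np.float32)
        grid[3, 3, 3] = 150.0            # 1-voxel speckle
        grid[10:12, 10:12, 10:12] = 150.0  # real 8-voxel particle
        stack = pos.Stack3D({"actin": np.zeros_like(grid), "pos": grid},
                            (0.25, 0.25, 0.25))
        particles = pos.segment_particles(stack, threshold_method=75.0,
                                          min_voxels=4)
        assert len(particles) == 1

    def test_empty_channel_gives_empty_set(self):
        grid = np.zeros((10, 10, 10), np.float32)
        stack = pos.Stack3D({"actin": grid, "pos": grid}, (0.25, 0.25, 0.25))
        assert len(pos.segment_particles(stack)) == 0


class TestClassifyParticles:
    def test_truth_classes_recovered(self, pos_stack_30_20):
        stack, truth = pos_stack_30_20
        surface = pos.build_apical_surface(stack)
        classified = pos.classify_particles(pos.segment_particles(stack),
                                            surface)
        counts = classified["class"].value_counts()
        assert counts["internalised"] == truth["n_internalised"] == 30
        assert counts["bound"] == truth["n_bound"] == 20

    def test_centroid_on_cutoff_is_bound(self):
        particles = pd.DataFrame({"particle_id": [1], "x_um": [1.0],
                                  "y_um": [1.0], "z_um": [9.1],
                                  "volume_um3": [0.5], "n_voxels": [10]})
        surface = pos.ApicalSurface(np.full((4, 4), 9.1), 9.1)
        out = pos.classify_particles(particles, surface)
        assert out["class"][0] == "bound"

    def test_internalised_count_monotone_in_cutoff(self, pos_stack_30_20):
        stack, _ = pos_stack_30_20
        particles = pos.segment_particles(stack)
        heights = np.full((4, 4), 1.0)
        counts = []
        for cutoff in (0.0, 5.0, 9.1, 20.0):
            surface = pos.ApicalSurface(heights, cutoff)
            n = (pos.classify_particles(particles, surface)["class"]
                 == "internalised").sum()
            counts.append(n)
        assert counts == sorted(counts)
        assert counts[-1] == len(particles)  # cutoff above all → all internal

    def test_partition_is_exhaustive_and_exclusive(self, pos_stack_30_20):
        stack, _ = pos_stack_30_20
        surface = pos.build_apical_surface(stack)
        classified = pos.classify_particles(pos.segment_particles(stack),
                                            surface)
        summary = pos.summarize_internalisation(classified)
        assert summary.n_total == len(classified)

    def test_noisy_stack_misclassification_rate(self):
        """≤2% of particles misclassified at 2% intensity noise (centroid
        margins of at least one voxel are enforced by the generator)."""
        wrong = total = 0
        for seed in range(20):
            stack, truth = syn.gen_pos_stack(n_internalised=10, n_bound=8,
                                             noise_level=0.02, seed=seed)
            surface = pos.build_apical_surface(stack)
            classified = pos.classify_particles(
                pos.segment_particles(stack, min_voxels=10), surface)
            n_int = (classified["class"] == "internalised").sum()
            wrong += abs(n_int - truth["n_internalised"])
            total += len(truth["particles"])
        assert wrong / total < 0.02


class TestSummarize:
    def test_mean_volume_arithmetic(self):
        volumes = [1.0, 2.0, 3.0] * 10
        df = pd.DataFrame({"volume_um3": volumes,
                           "class": ["internalised"] * 30})
        s = pos.summarize_internalisation(df)
        assert s.mean_internalised_volume_um3 == pytest.approx(2.0)
        assert np.isnan(s.mean_bound_volume_um3)

    def test_per_cell_normalisation(self):
        df = pd.DataFrame({"volume_um3": [1.0] * 3000,
                           "class": ["internalised"] * 3000})
        s = pos.summarize_internalisation(df, cell_count=3000)
        assert s.internalised_per_cell == pytest.approx(1.0)

    def test_zero_cell_count_rejected(self):
        df = pd.DataFrame({"volume_um3": [1.0], "class": ["bound"]})
        with pytest.raises(ValueError):
            pos.summarize_internalisation(df, cell_count=0)


class TestApicalActinArea:
    def test_flat_surface_equals_footprint(self):
        # 101 nodes at 1 µm pitch span 100 µm → 100 × 100 µm footprint
        h = np.full((101, 101), 5.0)
        assert pos.triangulated_area(h, 1.0, 1.0) == pytest.approx(10_000.0)

    def test_corrugation_strictly_increases_area(self):
        yy, xx = np.mgrid[0:101, 0:101]
        flat = np.full((101, 101), 5.0)
        wavy = 5.0 + 0.8 * np.sin(2 * np.pi * xx / 20) * np.sin(
            2 * np.pi * yy / 20)
        assert pos.triangulated_area(wavy, 1.0, 1.0) > \
            pos.triangulated_area(flat, 1.0, 1.0)

    def test_voxelised_surface_matches_analytic_mesh(self):
        """Height map recovered from a rasterised rough surface agrees with
        the analytic triangulated area of the truth heights within 1%."""
        dz, dy, dx = 0.05, 0.5, 0.5
        ny = nx = 51
        yy, xx = np.mgrid[0:ny, 0:nx]
        truth_heights = 6.0 + 1.0 * np.sin(2 * np.pi * xx * dx / 10) * \
            np.sin(2 * np.pi * yy * dy / 10)
        nz = int(10 / dz)
        actin = np.zeros((nz, ny, nx), np.float32)
        for y in range(ny):
            for x in range(nx):
                top = int(round(truth_heights[y, x] / dz)) - 1
                actin[max(top - 10, 0):top + 1, y, x] = 200.0
        quantised = (np.round(truth_heights / dz)) * dz
        stack = pos.Stack3D({"actin": actin, "pos": np.zeros_like(actin)},
                            (dz, dy, dx))
        measured = pos.apical_actin_area(stack, (0, nz),
                                         threshold_method=100.0)
        analytic = pos.triangulated_area(truth_heights, dy, dx)
        assert measured == pytest.approx(analytic, rel=0.01)
        # and the flat lower bound holds
        assert measured >= (ny - 1) * (nx - 1) * dy * dx

    def test_empty_slice_subset_rejected(self):
        actin = np.zeros((20, 10, 10), np.float32)
        actin[15] = 200.0
        stack = pos.Stack3D({"actin": actin, "pos": np.zeros_like(actin)},
                            (0.5, 0.5, 0.5))
        with pytest.raises(ValueError):
            pos.apical_actin_area(stack, (0, 5), threshold_method=100.0)
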