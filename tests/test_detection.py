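import numpy as np
import pytest

from neuromosaic.detection import (
    DetectionConfig, DetectedCell, intensity_stats, compute_threshold,
    segment_cells, detect, classify_by_size, cells_to_pattern,
)
from neuromosaic.geometry import Box3D, PointPattern
from neuromosaic.images import VolumeImage
from neuromosaic.synthetic import BlobClassModel, render_volume


def make_volume(data, voxel=1.0):
    return VolumeImage(np.asarray(data, dtype=float), voxel)


class TestIntensityStats:
    def test_hand_computed_moments(self):
        vol = make_volume(np.array([0.0, 0.0, 0.0, 4.0]).reshape(1, 1, 4))
        s = intensity_stats(vol)
        assert s.mean == pytest.approx(1.0)
        assert s.std == pytest.approx(np.sqrt(3.0))  # population convention

    def test_constant_volume_flags_undefined_skewness(self):
        s = intensity_stats(make_volume(np.full((3, 3, 3), 7.0)))
        assert (s.mean, s.std, s.skewness) == (7.0, 0.0, 0.0)
        assert not s.skewness_defined

    def test_symmetric_distribution_has_zero_skewness(self):
        data = np.concatenate([np.zeros(500), np.ones(500)]).reshape(10, 10, 10)
        s = intensity_stats(make_volume(data))
        assert s.skewness == pytest.approx(0.0, abs=1e-12)
        assert s.skewness_defined

    def test_histogram_counts_cover_all_voxels(self, rng):
        vol = make_volume(rng.normal(size=(8, 8, 8)))
        s = intensity_stats(vol)
        assert s.histogram[1].sum() == 512

    def test_empty_mask_rejected(self):
        vol = make_volume(np.ones((2, 2, 2)))
        with pytest.raises(ValueError, match="no voxels"):
            intensity_stats(vol, mask=np.zeros((2, 2, 2), dtype=bool))


class TestThreshold:
    def test_mean_plus_k_sigma(self):
        vol = make_volume(np.array([0.0, 0.0, 0.0, 4.0]).reshape(1, 1, 4))
        s = intensity_stats(vol)
        assert compute_threshold(s, 2.0) == pytest.approx(1.0 + 2.0 * np.sqrt(3.0))

    def test_degenerate_cases_reduce_to_mean(self):
        s = intensity_stats(make_volume(np.full((2, 2, 2), 5.0)))
        assert compute_threshold(s, 2.0) == 5.0  # zero spread
        vol = make_volume(np.arange(8.0).reshape(2, 2, 2))
        s2 = intensity_stats(vol)
        assert compute_threshold(s2, 0.0) == s2.mean


class TestSegmentation:
    def test_all_zero_volume_yields_no_cells(self):
        assert segment_cells(make_volume(np.zeros((10, 10, 10)))) == []

    def test_single_large_blob_recovered_at_ground_truth(self):
        box = Box3D.cube(100.0)
        pat = PointPattern([[50.0, 50.0, 50.0]], box)
        model = {"motor_neuron": BlobClassModel((40.0, 40.0), 0.5, 100.0, 200.0)}
        vol, _ = render_volume(pat, model, voxel_size=1.0, noise_sigma=0.0, seed=0)
        cells = segment_cells(vol)
        assert len(cells) == 1
        np.testing.assert_allclose(cells[0].centroid, [50.0, 50.0, 50.0], atol=1.0)
        assert cells[0].volume >= 343.0

    def test_small_blob_removed_by_size_filter(self):
        # a 3 μm sphere is ~14 μm³, far below the 7×7×7 μm³ = 343 μm³ cut
        box = Box3D.cube(50.0)
        pat = PointPattern([[25.0, 25.0, 25.0]], box)
        model = {"motor_neuron": BlobClassModel((3.0, 3.0), 0.5, 100.0, 200.0)}
        vol, _ = render_volume(pat, model, voxel_size=1.0, noise_sigma=0.0, seed=0)
        assert segment_cells(vol) == []

    def test_threshold_monotonicity_in_k(self):
        # non-overlapping somata, no noise: raising the threshold can only
        # shrink components, so the detected count is non-increasing in k
        # (noise breaks this at low k, where the background percolates into
        # one giant component)
        from neuromosaic.synthetic import gen_hardcore
        box = Box3D.cube(250.0)
        pat = gen_hardcore(10, 55.0, box, 4)
        vol, _ = render_volume(pat, voxel_size=2.0, noise_sigma=0.0, seed=5)
        counts = [len(segment_cells(vol, DetectionConfig(threshold_k=k)))
                  for k in (0.5, 1.0, 2.0, 4.0, 8.0)]
        assert counts == sorted(counts, reverse=True)

    def test_every_cell_satisfies_volume_filter(self):
        box = Box3D.cube(120.0)
        pts = np.random.default_rng(6).random((8, 3)) * 80 + 20
        vol, _ = render_volume(PointPattern(pts, box), voxel_size=2.0,
                               noise_sigma=20.0, seed=7)
        for cell in segment_cells(vol):
            assert cell.volume >= 343.0

    def test_two_pass_refinement_runs(self):
        box = Box3D.cube(100.0)
        pat = PointPattern([[50.0, 50.0, 50.0]], box)
        vol, _ = render_volume(pat, voxel_size=2.0, noise_sigma=0.0, seed=0)
        res = detect(vol, DetectionConfig(two_pass=True))
        assert res.threshold > 0


class TestSizeClasses:
    @pytest.mark.parametrize("diameter,expected", [
        (40.0, "motor_neuron"),   # 30–50 μm
        (15.0, "interneuron"),    # 10–20 μm
        (5.0, "glia_like"),       # < 7 μm
        (25.0, "unclassified"),   # gap between stated ranges
        (30.0, "motor_neuron"),   # half-open interval includes the min
        (50.0, "unclassified"),   # ... and excludes the max
    ])
    def test_diameter_intervals(self, diameter, expected):
        vol = (np.pi / 6.0) * diameter ** 3
        cell = DetectedCell(np.zeros(3), 1, vol, diameter)
        assert classify_by_size([cell])[0].size_class == expected

    def test_overlapping_intervals_rejected_at_config_time(self):
        with pytest.raises(ValueError, match="overlap"):
            DetectionConfig(size_class_bounds={"a": (0, 10), "b": (5, 20)})


class TestCellsToPattern:
    def test_empty_list_gives_empty_pattern(self, box100):
        assert cells_to_pattern([], box100).n == 0

    def test_class_filter_keeps_only_requested(self, box100):
        cells = [
            DetectedCell(np.array([10.0, 10, 10]), 1, 400, 40, "motor_neuron"),
            DetectedCell(np.array([20.0, 20, 20]), 1, 400, 15, "interneuron"),
            DetectedCell(np.array([30.0, 30, 30]), 1, 400, 45, "motor_neuron"),
        ]
        pat = cells_to_pattern(cells, box100, class_filter="motor_neuron")
        assert pat.n == 2 and set(pat.labels) == {"motor_neuron"}

    def test_centroid_outside_box_is_an_error(self, box100):
        cells = [DetectedCell(np.array([150.0, 10, 10]), 1, 400, 40)]
        with pytest.raises(ValueError, match="outside"):
            cells_to_pattern(cells, box100)

    def test_rendered_multi_blob_scenario_fully_recovered(self):
        from neuromosaic.synthetic import gen_hardcore
        box = Box3D.cube(300.0)
        pat = gen_hardcore(20, 55.0, box, 13)
        vol, _ = render_volume(pat, voxel_size=2.0, noise_sigma=0.0, seed=14)
        cells = segment_cells(vol)
        assert cells_to_pattern(cells, box).n == 20
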