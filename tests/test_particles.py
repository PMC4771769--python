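"""Cluster detection, morphometry, gating and per-ROI statistics."""

import math

import numpy as np
import pytest

from _oracles import canonical_partition, flood_fill_labels, marching_squares_perimeter
from aisquant.imaging import BinaryMask, Location, Roi
from aisquant.particles import (
    Cluster,
    filter_clusters,
    label_clusters,
    measure_cluster,
    roi_stats,
)


def _full_roi(shape, label=1, loc=Location.AIS):
    return Roi(np.ones(shape, dtype=bool), label, loc)


class TestLabeling:
    def test_empty_mask_gives_no_clusters(self):
        mask = BinaryMask(np.zeros((16, 16), dtype=bool))
        assert label_clusters(mask, _full_roi((16, 16)), 64.0) == []

    def test_diagonal_pixels_split_by_connectivity(self):
        m = np.zeros((8, 8), dtype=bool)
        m[3, 3] = m[4, 4] = True
        mask = BinaryMask(m)
        assert len(label_clusters(mask, _full_roi((8, 8)), 64.0, connectivity=4)) == 2
        assert len(label_clusters(mask, _full_roi((8, 8)), 64.0, connectivity=8)) == 1

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_partition_matches_flood_fill_oracle(self, connectivity, rng):
        roi = _full_roi((64, 64))
        for _ in range(40):
            m = rng.random((64, 64)) < 0.35
            clusters = label_clusters(BinaryMask(m), roi, 64.0, connectivity)
            got = {frozenset(map(tuple, c.pixels)) for c in clusters}
            want = canonical_partition(flood_fill_labels(m, connectivity))
            assert got == want

    def test_clusters_clipped_to_roi(self):
        m = np.ones((10, 10), dtype=bool)
        half = np.zeros((10, 10), dtype=bool)
        half[:, :5] = True
        clusters = label_clusters(BinaryMask(m), Roi(half, 1, Location.AIS), 64.0)
        assert sum(c.n_pixels for c in clusters) == 50


class TestMorphometry:
    def test_single_pixel_area_at_64nm(self):
        c = measure_cluster(np.array([[3, 3]]), 64.0)
        assert c.area_um2 == pytest.approx(0.004096, abs=1e-12)

    def test_disc_is_circular(self):
        yy, xx = np.mgrid[-45:46, -45:46]
        disc = (yy**2 + xx**2) <= 40**2
        c = measure_cluster(np.argwhere(disc), 64.0)
        assert c.circularity >= 0.95
        # sanity: the chain-code perimeter agrees with a marching-squares
        # oracle (which itself overestimates smooth contours by a few percent
        # on binary rasters, hence the loose band)
        oracle = marching_squares_perimeter(disc) * 0.064
        assert c.perimeter_um == pytest.approx(oracle, rel=0.10)

    def test_elongated_line_fails_circularity_gate(self):
        line = np.array([[5, c] for c in range(2, 42)])  # 1 x 40 pixels
        c = measure_cluster(line, 64.0)
        assert c.circularity < 0.10

    def test_empty_pixel_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            measure_cluster(np.empty((0, 2)), 64.0)


def _fake_cluster(area_um2, circ):
    n = max(int(round(area_um2 / 0.004096)), 1)
    return Cluster(np.zeros((n, 2), dtype=np.intp), area_um2, 1.0, circ, (0.0, 0.0))


class TestFiltering:
    def test_gates_are_closed_intervals(self):
        planted = [0.01, 0.05, 5.0, 12.0]
        clusters = [_fake_cluster(a, 0.9) for a in planted]
        kept = filter_clusters(clusters)
        assert sorted(c.area_um2 for c in kept) == [0.05, 5.0]

    def test_single_pixel_cluster_removed_by_area_gate(self):
        c = measure_cluster(np.array([[0, 0]]), 64.0)
        assert filter_clusters([c]) == []

    def test_interior_cluster_retained(self):
        assert len(filter_clusters([_fake_cluster(1.0, 0.9)])) == 1

    def test_inverted_gates_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            filter_clusters([], area_gate_um2=(10.0, 0.05))

    def test_filtering_is_monotone_in_gates(self, rng):
        clusters = [_fake_cluster(a, c) for a, c in
                    zip(rng.uniform(0.0, 15.0, 200), rng.uniform(0.0, 1.0, 200))]
        wide = filter_clusters(clusters, (0.05, 10.0), (0.1, 1.0))
        narrow = filter_clusters(clusters, (0.1, 5.0), (0.3, 0.9))
        assert set(map(id, narrow)) <= set(map(id, wide))


class TestRoiStats:
    def test_zero_puncta_rule(self):
        roi = _full_roi((50, 50))
        s = roi_stats([], roi, 64.0)
        assert s.n_clusters == 0
        assert s.density == 0.0
        assert math.isnan(s.mean_size_um2)
        assert s.percent_area == 0.0

    def test_definition_arithmetic(self):
        # 100 um^2 ROI at 1000 nm pixels = 10x10 px; 5 clusters covering 10 um^2
        roi = Roi(np.ones((10, 10), dtype=bool), 1, Location.AIS)
        clusters = [_fake_cluster_px(2) for _ in range(5)]
        s = roi_stats(clusters, roi, 1000.0)
        assert s.density == pytest.approx(5.0)
        assert s.percent_area == pytest.approx(10.0)
        assert s.mean_size_um2 == pytest.approx(2.0)

    def test_percent_area_identity(self, clean_scene):
        """percent_area * roi_area / 100 equals the summed cluster areas."""
        from aisquant.preprocess import triangle_threshold
        from aisquant.particles import label_clusters

        thr = triangle_threshold(clean_scene.channels["alpha2"])
        px = clean_scene.config.pixel_size_nm
        for roi in clean_scene.rois[:4]:
            clusters = label_clusters(thr.mask, roi, px)
            s = roi_stats(clusters, roi, px)
            assert s.percent_area * s.roi_area_um2 / 100.0 == pytest.approx(
                sum(c.area_um2 for c in clusters), rel=1e-9
            )

    def test_planted_density_recovered(self):
        """Mean recovered AIS density within 15% of planted over 40 ROIs."""
        from aisquant.synthetic import SceneConfig, generate_scene
        from aisquant.protocols import quantify_scene

        cfg = SceneConfig(image_size_px=(640, 320), pixel_size_nm=128.0, n_ais=20,
                          ais_length_um=12.0, ais_width_um=1.6, ais_wiggle_um=0.5,
                          ais_puncta_density_per_100um2=30.0, channels=("alpha2",),
                          seed=11)
        scene = generate_scene(cfg)
        ais, non = quantify_scene(scene)
        truth = scene.truth.roi_truth
        planted = truth[truth.location_class == "AIS"].density_per_100um2.mean()
        measured = np.mean([s.density for s in ais])
        assert abs(measured - planted) / planted < 0.15
        assert len(ais) + len(non) == 40


def _fake_cluster_px(area_um2):
    # cluster whose pixel count matches its area at 1000 nm pixels
    n = int(round(area_um2))
    return Cluster(np.zeros((n, 2), dtype=np.intp), float(area_um2), 1.0, 0.9, (0.0, 0.0))
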