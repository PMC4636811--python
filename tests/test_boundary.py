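"""Cluster grouping, circle fitting, and the end-to-end detector."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mammocalc import (
    Cluster,
    GrayImage,
    PhantomSpec,
    cluster_foreground,
    detect,
    draw_overlay,
    enclosing_circle,
    make_phantom,
)


def brute_merge_oracle(mask, link):
    """Reference grouping: 8-connected components, then transitive
    merging by pairwise minimum distance, as frozen pixel sets."""
    from scipy import ndimage

    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    comps = [np.argwhere(labels == i + 1) for i in range(n)]
    merged = True
    groups = [set(map(tuple, c)) for c in comps]
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a = np.array(sorted(groups[i]))
                b = np.array(sorted(groups[j]))
                if cdist(a, b).min() <= link:
                    groups[i] |= groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return {frozenset(g) for g in groups}


class TestClusterForeground:
    def test_empty_mask(self, cfg):
        assert cluster_foreground(np.zeros((10, 10), bool), cfg) == []

    def test_diagonal_pixels_are_one_cluster(self, cfg):
        mask = np.zeros((10, 10), bool)
        mask[3, 3] = mask[4, 4] = True
        clusters = cluster_foreground(mask, cfg)
        assert len(clusters) == 1
        assert clusters[0].size == 2

    def test_distant_blobs_stay_separate(self, cfg):
        mask = np.zeros((120, 120), bool)
        mask[5:8, 5] = True
        mask[105:108, 105] = True  # ~140 px apart >> link distance 30
        assert len(cluster_foreground(mask, cfg)) == 2

    def test_nearby_components_merge(self, cfg):
        mask = np.zeros((60, 60), bool)
        mask[10, 10] = True
        mask[10, 30] = True  # 20 px apart <= 30
        assert len(cluster_foreground(mask, cfg)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pairwise_merge_oracle(self, seed, cfg):
        rng = np.random.default_rng(seed)
        mask = np.zeros((80, 80), bool)
        pts = rng.integers(0, 80, size=(25, 2))
        mask[pts[:, 0], pts[:, 1]] = True
        small = dataclasses.replace(cfg, cluster_link_distance=12.0)
        ours = {
            frozenset(map(tuple, c.pixels)) for c in cluster_foreground(mask, small)
        }
        assert ours == brute_merge_oracle(mask, 12.0)

    def test_clusters_partition_foreground(self, cfg):
        rng = np.random.default_rng(99)
        mask = rng.random((50, 50)) > 0.93
        clusters = cluster_foreground(mask, cfg)
        seen = np.zeros_like(mask, dtype=int)
        for c in clusters:
            seen[c.pixels[:, 0], c.pixels[:, 1]] += 1
        np.testing.assert_array_equal(seen, mask.astype(int))

    def test_order_is_topmost_then_leftmost(self, cfg):
        mask = np.zeros((100, 100), bool)
        mask[50, 90] = True
        mask[50, 5] = True
        mask[2, 60] = True
        small = dataclasses.replace(cfg, cluster_link_distance=1.0)
        anchors = [tuple(c.pixels[0]) for c in cluster_foreground(mask, small)]
        assert anchors == [(2, 60), (50, 5), (50, 90)]


class TestEnclosingCircle:
    def test_single_pixel(self, cfg):
        d = enclosing_circle(Cluster(pixels=np.array([[10, 10]])), cfg)
        assert (d.center_row, d.center_col) == (10.0, 10.0)
        assert d.radius == cfg.circle_margin

    def test_two_pixel_symmetry(self, cfg):
        d = enclosing_circle(Cluster(pixels=np.array([[0, 0], [0, 10]])), cfg)
        assert (d.center_row, d.center_col) == (0.0, 5.0)
        assert d.radius == 5.0 + cfg.circle_margin

    @pytest.mark.parametrize("seed", range(4))
    def test_containment(self, seed, cfg):
        rng = np.random.default_rng(seed)
        pix = rng.integers(0, 60, size=(15, 2))
        d = enclosing_circle(Cluster(pixels=pix), cfg)
        dists = np.hypot(pix[:, 0] - d.center_row, pix[:, 1] - d.center_col)
        assert (dists <= d.radius).all()

    def test_empty_cluster_raises(self, cfg):
        with pytest.raises(ValueError):
            enclosing_circle(Cluster(pixels=np.empty((0, 2), int)), cfg)


class TestDetect:
    def test_constant_image_reported_normal(self, cfg):
        is_normal, dets, ir = detect(GrayImage(np.full((64, 64), 90.0)), cfg)
        assert is_normal and dets == [] and ir.sum() == 0

    def test_phantom_cluster_recovered(self, cfg):
        spec = PhantomSpec(seed=42, n_clusters=1)
        img, truth = make_phantom(spec, abnormal=True)
        is_normal, dets, ir = detect(img, cfg)
        assert not is_normal and len(dets) >= 1
        # some detection circle covers the planted centroid
        centroid = np.argwhere(truth.regions[0]).mean(axis=0)
        covered = any(
            np.hypot(d.center_row - centroid[0], d.center_col - centroid[1])
            <= d.radius
            for d in dets
        )
        assert covered

    def test_two_separated_clusters_give_two_detections(self, cfg):
        spec = PhantomSpec(seed=5, n_clusters=0)
        img, _ = make_phantom(spec, abnormal=False)
        from mammocalc import plant_cluster

        rng = np.random.default_rng(7)
        tight = dataclasses.replace(spec, cluster_spread=8.0)
        img, m1 = plant_cluster(img, tight, (64, 64), rng=rng)
        img, m2 = plant_cluster(img, tight, (190, 190), rng=rng)
        is_normal, dets, ir = detect(img, cfg)
        assert not is_normal
        assert len(dets) == 2

    def test_determinism(self, cfg):
        img, _ = make_phantom(PhantomSpec(seed=8), abnormal=True)
        r1 = detect(img, cfg)
        r2 = detect(img, cfg)
        assert r1[0] == r2[0] and len(r1[1]) == len(r2[1])
        np.testing.assert_array_equal(r1[2], r2[2])
        for d1, d2 in zip(r1[1], r2[1]):
            assert (d1.center_row, d1.center_col, d1.radius) == (
                d2.center_row, d2.center_col, d2.radius,
            )

    def test_skip_prefilter_forces_processing(self, cfg):
        img = GrayImage(
            np.clip(100 + 5 * np.random.default_rng(3).standard_normal((64, 64)), 0, 255)
        )
        assert detect(img, cfg)[0] is True
        is_normal, _, _ = detect(img, cfg, skip_prefilter=True)
        assert is_normal is False


class TestDrawOverlay:
    def test_no_detections_is_identity(self, cfg):
        img = GrayImage(np.random.default_rng(0).random((20, 20)) * 255)
        out = draw_overlay(img, [])
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_outline_lies_near_radius(self, cfg):
        img = GrayImage(np.zeros((60, 60)))
        det = enclosing_circle(Cluster(pixels=np.array([[30, 30]])), cfg)
        out = draw_overlay(img, [det])
        marked = np.argwhere(out.pixels == 255.0)
        assert len(marked) > 0
        dists = np.hypot(marked[:, 0] - 30, marked[:, 1] - 30)
        assert np.abs(dists - det.radius).max() <= 1.0

    def test_idempotent(self, cfg):
        img = GrayImage(np.zeros((60, 60)))
        det = enclosing_circle(Cluster(pixels=np.array([[30, 30]])), cfg)
        once = draw_overlay(img, [det])
        twice = draw_overlay(once, [det])
        np.testing.assert_array_equal(once.pixels, twice.pixels)
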