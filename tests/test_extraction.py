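"""Colony extraction chain: masks, artifact removal, segmentation, alpha."""

import numpy as np
import pytest

from petrisynth.datamodel import AnnotatedDish, BoundingBox, ColonyAnnotation, ValidationError
from petrisynth.extraction import (
    ExtractionConfig,
    blending_mask,
    compose_alpha,
    cut_cluster,
    denoise,
    extract_cluster,
    remove_dark_artifacts,
    segment_chan_vese,
)


def _dish_with_boxes(boxes, size=120, value=150):
    img = np.full((size, size, 3), value, dtype=np.uint8)
    anns = [ColonyAnnotation(b, "E.coli", i) for i, b in enumerate(boxes)]
    return AnnotatedDish(img, anns, "synthetic")


class TestCutCluster:
    def test_single_box_zero_margin(self):
        dish = _dish_with_boxes([BoundingBox(20, 30, 10, 10)])
        frag, m_bx, local = cut_cluster(dish, [0], margin=0)
        assert frag.shape == (10, 10, 3)
        assert m_bx.all()
        assert local == [BoundingBox(0, 0, 10, 10)]

    def test_gap_between_disjoint_member_boxes(self):
        # boxes 0 and 2 disjoint in y, linked through box 1
        boxes = [
            BoundingBox(10, 10, 10, 10),
            BoundingBox(15, 18, 10, 10),
            BoundingBox(40, 10, 10, 10),
        ]
        dish = _dish_with_boxes(boxes)
        frag, m_bx, local = cut_cluster(dish, [0, 2], margin=0)
        # oracle: rasterize member boxes independently
        expected = np.zeros(frag.shape[:2], dtype=bool)
        for b in local:
            expected[b.y : b.y2, b.x : b.x2] = True
        assert (m_bx == expected).all()
        assert not m_bx[:, 12:28].any()  # the gap between the two boxes

    def test_mbx_pixelcount_inclusion_exclusion(self):
        # two overlapping boxes: |A ∪ B| = |A| + |B| - |A ∩ B|
        a, b = BoundingBox(10, 10, 12, 8), BoundingBox(16, 12, 12, 8)
        dish = _dish_with_boxes([a, b])
        _, m_bx, _ = cut_cluster(dish, [0, 1], margin=3)
        inter_w = max(0, min(a.x2, b.x2) - max(a.x, b.x))
        inter_h = max(0, min(a.y2, b.y2) - max(a.y, b.y))
        assert m_bx.sum() == a.area + b.area - inter_w * inter_h

    def test_margin_truncated_at_corner(self):
        dish = _dish_with_boxes([BoundingBox(0, 0, 10, 10)])
        frag, _, _ = cut_cluster(dish, [0], margin=5)
        assert frag.shape == (15, 15, 3)  # margin clipped at the image corner


class TestRemoveDarkArtifacts:
    def test_identity_without_dark_pixels(self):
        rgb = np.full((30, 30, 3), 180, dtype=np.uint8)
        out, m_d = remove_dark_artifacts(rgb, ExtractionConfig())
        assert not m_d.any()
        assert (out == rgb).all()

    def test_single_masked_pixel_takes_unique_donor_value(self):
        rgb = np.full((21, 21, 3), 200, dtype=np.uint8)
        rgb[10, 10] = (5, 5, 5)  # one dark speck
        cfg = ExtractionConfig(dark_dilate_radius=0)
        out, m_d = remove_dark_artifacts(rgb, cfg)
        assert m_d.sum() == 1
        assert tuple(out[10, 10]) == (200, 200, 200)

    def test_replacement_values_come_from_valid_pixels(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(60, 256, (40, 40, 3), dtype=np.uint8)
        rgb[5:9, 5:9] = (10, 10, 10)
        cfg = ExtractionConfig()
        out, m_d = remove_dark_artifacts(rgb, cfg)
        valid_values = {tuple(v) for v in rgb[~m_d].reshape(-1, 3)}
        for v in out[m_d].reshape(-1, 3):
            assert tuple(v) in valid_values
        # untouched outside the mask, bit-exactly
        assert (out[~m_d] == rgb[~m_d]).all()

    def test_seeded_walk_reproducible(self):
        rng = np.random.default_rng(1)
        rgb = rng.integers(60, 256, (30, 30, 3), dtype=np.uint8)
        rgb[10:14, 10:20] = (0, 0, 0)
        cfg = ExtractionConfig(rng_seed=77)
        out1, _ = remove_dark_artifacts(rgb, cfg)
        out2, _ = remove_dark_artifacts(rgb, cfg)
        assert (out1 == out2).all()

    def test_all_masked_errors(self):
        rgb = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValidationError, match="no valid pixels"):
            remove_dark_artifacts(rgb, ExtractionConfig())


class TestDenoise:
    def test_constant_image_unchanged(self):
        rgb = np.full((32, 32, 3), 123, dtype=np.uint8)
        assert (denoise(rgb, ExtractionConfig()) == rgb).all()

    def test_reduces_salt_and_pepper_mad(self):
        rng = np.random.default_rng(0)
        clean = np.full((64, 64, 3), 128, dtype=np.uint8)
        noisy = clean.copy()
        hits = rng.uniform(size=(64, 64)) < 0.01
        noisy[hits] = rng.choice([0, 255], size=(hits.sum(), 3)).astype(np.uint8)
        out = denoise(noisy, ExtractionConfig())
        mad_before = np.abs(noisy.astype(int) - clean.astype(int)).mean()
        mad_after = np.abs(out.astype(int) - clean.astype(int)).mean()
        assert mad_after < mad_before

    def test_zero_strength_is_null_filter(self):
        rng = np.random.default_rng(2)
        rgb = rng.integers(0, 256, (20, 20, 3), dtype=np.uint8)
        out = denoise(rgb, ExtractionConfig(nlm_strength=0.0))
        assert np.abs(out.astype(int) - rgb.astype(int)).max() <= 1


class TestSegmentChanVese:
    @staticmethod
    def _disk_image(size=80, radius=22, fg=200, bg=50):
        yy, xx = np.mgrid[0:size, 0:size]
        disk = (yy - size / 2) ** 2 + (xx - size / 2) ** 2 <= radius**2
        img = np.full((size, size, 3), bg, dtype=np.uint8)
        img[disk] = fg
        return img, disk

    def test_bright_disk_iou(self):
        img, disk = self._disk_image()
        cfg = ExtractionConfig(seg_dilate_radius=0)
        m_s = segment_chan_vese(img, cfg)
        iou = (m_s & disk).sum() / (m_s | disk).sum()
        assert iou >= 0.95

    def test_constant_fragment_empty_mask(self):
        img = np.full((40, 40, 3), 90, dtype=np.uint8)
        with pytest.warns(UserWarning, match="constant fragment"):
            m_s = segment_chan_vese(img, ExtractionConfig())
        assert not m_s.any()

    def test_dilated_mask_is_superset(self):
        img, _ = self._disk_image()
        undilated = segment_chan_vese(img, ExtractionConfig(seg_dilate_radius=0))
        dilated = segment_chan_vese(img, ExtractionConfig(seg_dilate_radius=3))
        assert (dilated | undilated == dilated).all()


class TestBlendingMask:
    def test_two_color_closed_form(self):
        # background color A outside m_s, color B inside: distances are 0 and d_max
        rgb = np.full((20, 20, 3), 200, dtype=np.uint8)
        m_s = np.zeros((20, 20), dtype=bool)
        m_s[5:15, 5:15] = True
        rgb[m_s] = (30, 60, 90)
        m_b = blending_mask(rgb, m_s)
        assert (m_b[~m_s] == 0).all()
        assert (m_b[m_s] == 255).all()

    def test_all_foreground_errors(self):
        rgb = np.full((10, 10, 3), 100, dtype=np.uint8)
        with pytest.raises(ValidationError, match="no background"):
            blending_mask(rgb, np.ones((10, 10), dtype=bool))


class TestComposeAlpha:
    def test_annihilator_and_identity(self):
        shape = (12, 12)
        ones = np.ones(shape, dtype=bool)
        full = np.full(shape, 255, dtype=np.uint8)
        assert not compose_alpha(ones, np.zeros(shape, bool), full).any()
        assert (compose_alpha(ones, ones, full) == 255).all()

    def test_matches_per_pixel_triple_product(self):
        rng = np.random.default_rng(4)
        m_bx = rng.uniform(size=(15, 17)) < 0.6
        m_s = rng.uniform(size=(15, 17)) < 0.6
        m_b = rng.integers(0, 256, (15, 17)).astype(np.uint8)
        alpha = compose_alpha(m_bx, m_s, m_b)
        for i in range(15):
            for j in range(17):
                assert alpha[i, j] == int(m_bx[i, j]) * int(m_s[i, j]) * int(m_b[i, j])

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError, match="shape"):
            compose_alpha(np.ones((3, 3), bool), np.ones((4, 4), bool),
                          np.ones((3, 3), np.uint8))


class TestExtractCluster:
    def test_full_chain_on_fixture_dish(self, small_dish):
        dish, truth_masks = small_dish
        from petrisynth.clusters import cluster_boxes

        clusters = cluster_boxes([a.bbox for a in dish.annotations])
        cfg = ExtractionConfig()
        cut = extract_cluster(dish, clusters[0], cfg)
        assert cut is not None
        # cardinality: one box and one mask per member colony
        assert len(cut.per_colony_boxes) == len(clusters[0])
        assert len(cut.per_colony_masks) == len(clusters[0])
        # alpha is zero outside the union of member boxes (m_bx factor)
        assert not cut.alpha[~cut.m_bx].any()
        # alpha equals the Hadamard product of its factors
        expected = (
            cut.m_bx.astype(np.uint16) * cut.m_s.astype(np.uint16) * cut.m_b
        ).astype(np.uint8)
        assert (cut.alpha == expected).all()

    def test_reproducible_under_seed(self, small_dish):
        dish, _ = small_dish
        from petrisynth.clusters import cluster_boxes

        cl = cluster_boxes([a.bbox for a in dish.annotations])[0]
        cfg = ExtractionConfig(rng_seed=5)
        a = extract_cluster(dish, cl, cfg)
        b = extract_cluster(dish, cl, cfg)
        assert (a.rgb == b.rgb).all() and (a.alpha == b.alpha).all()
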