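"""Contour fusion, stroma inversion, mask cleaning, CRF refinement."""

import dataclasses

import numpy as np
import pytest
from scipy import ndimage

from glandseg import masks, metrics, postprocess, synth
from glandseg.model import ProbabilityMaps

CFG = postprocess.PostprocessConfig(min_area=50, apply_crf=False)


def two_blob_fixture():
    """Two blobs 6 px apart joined by a bridge, with a contour line across
    the bridge — the canonical separation case."""
    obj = np.zeros((20, 20))
    obj[4:16, 2:8] = 0.9    # left blob
    obj[4:16, 14:20] = 0.9  # right blob, 6 px gap
    obj[9:11, 8:14] = 0.9   # bridge joins them into one component
    cnt = np.zeros((20, 20))
    cnt[8:12, 10:12] = 0.9  # contour line across the bridge
    return ProbabilityMaps(object_prob=obj, contour_prob=cnt)


class TestFuseGlandContour:
    def test_no_contour_gives_connected_components(self):
        obj = np.zeros((16, 16))
        obj[2:6, 2:6] = 0.9
        obj[10:14, 10:14] = 0.9
        maps = ProbabilityMaps(obj, np.zeros((16, 16)))
        out = postprocess.fuse_gland_contour(maps, CFG)
        assert out.max() == 2
        expected, _ = ndimage.label(obj >= 0.5, np.ones((3, 3)))
        assert np.array_equal(out > 0, expected > 0)

    def test_two_blob_fixture_separates(self):
        out = postprocess.fuse_gland_contour(two_blob_fixture(), CFG)
        assert out.max() == 2

    def test_empty_object_map(self):
        maps = ProbabilityMaps(np.zeros((8, 8)), np.ones((8, 8)))
        assert postprocess.fuse_gland_contour(maps, CFG).max() == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_label_count_matches_separated_components(self, seed):
        """Labels are exactly the components of the contour-separated map:
        boundary recovery never creates, merges, or drops labels, and the
        final footprint never exceeds the thresholded object map."""
        rng = np.random.default_rng(seed)
        obj = ndimage.gaussian_filter(rng.random((32, 32)), 2)
        obj = (obj - obj.min()) / (np.ptp(obj) + 1e-12)
        cnt = ndimage.gaussian_filter(rng.random((32, 32)), 1)
        cnt = (cnt - cnt.min()) / (np.ptp(cnt) + 1e-12)
        maps = ProbabilityMaps(obj, cnt)
        cfg = postprocess.PostprocessConfig(min_area=0, apply_crf=False)
        out = postprocess.fuse_gland_contour(maps, cfg)
        gland_bin = obj >= cfg.t_object
        contour = ndimage.binary_dilation(cnt >= cfg.t_contour, masks.CROSS,
                                          iterations=cfg.dilation_iters)
        n_separated = ndimage.label(gland_bin & ~contour, np.ones((3, 3)))[1]
        assert out.max() == n_separated
        assert not ((out > 0) & ~gland_bin).any()


class TestGlandFromStroma:
    def test_all_stroma_gives_empty(self):
        maps = ProbabilityMaps(np.ones((8, 8)), np.zeros((8, 8)))
        assert postprocess.gland_from_stroma(maps, CFG).max() == 0

    def test_inversion_degeneracy_full_frame(self):
        maps = ProbabilityMaps(np.zeros((8, 8)), np.zeros((8, 8)))
        out = postprocess.gland_from_stroma(maps, CFG)
        assert out.max() == 1 and (out > 0).all()

    @pytest.mark.parametrize("seed", [2, 6])
    def test_generator_round_trip(self, seed, small_params):
        params = dataclasses.replace(small_params, seed=seed)
        tile, inst = synth.generate_tissue(params)
        part = masks.derive_stroma_mask(tile, inst)
        pair = masks.stroma_targets(part)
        maps = ProbabilityMaps(pair.object_mask.astype(float),
                               pair.contour_mask.astype(float))
        rec = postprocess.clean_mask(
            postprocess.gland_from_stroma(maps, CFG, tile=tile), CFG)
        assert metrics.dice_coefficient(inst > 0, rec > 0) > 0.98

    def test_path_consistency(self, small_tile):
        """Both paths applied to the same ground-truth partition agree."""
        tile, inst = small_tile
        part = masks.derive_stroma_mask(tile, inst)
        spair = masks.stroma_targets(part)
        gpair = masks.gland_targets(inst)
        s_maps = ProbabilityMaps(spair.object_mask.astype(float),
                                 spair.contour_mask.astype(float))
        g_maps = ProbabilityMaps(gpair.object_mask.astype(float),
                                 gpair.contour_mask.astype(float))
        via_stroma = postprocess.clean_mask(
            postprocess.gland_from_stroma(s_maps, CFG, tile=tile), CFG)
        via_gland = postprocess.clean_mask(
            postprocess.fuse_gland_contour(g_maps, CFG), CFG)
        assert metrics.dice_coefficient(via_stroma > 0, via_gland > 0) > 0.95


class TestCleanMask:
    def test_small_components_removed(self):
        inst = np.zeros((40, 40), int)
        inst[1:3, 1:6] = 1          # area 10 < 50
        inst[10:35, 10:30] = 2      # area 500
        out = postprocess.clean_mask(inst, CFG)
        assert set(np.unique(out)) == {0, 1}
        assert (out == 1).sum() >= 500

    def test_ring_filled_to_disk(self):
        inst = np.zeros((30, 30), int)
        rr, cc = np.mgrid[0:30, 0:30]
        d2 = (rr - 15) ** 2 + (cc - 15) ** 2
        ring = (d2 <= 100) & (d2 >= 36)
        inst[ring] = 1
        hole = (d2 < 36).sum()
        out = postprocess.clean_mask(inst, CFG)
        assert (out == 1).sum() == ring.sum() + hole

    def test_empty_passthrough(self):
        assert postprocess.clean_mask(np.zeros((5, 5), int), CFG).max() == 0

    def test_idempotent(self, small_tile):
        tile, inst = small_tile
        once = postprocess.clean_mask(inst, CFG)
        twice = postprocess.clean_mask(once, CFG)
        assert np.array_equal(once, twice)


class TestCRF:
    def test_saturated_edge_consistent_unchanged(self, small_tile):
        tile, inst = small_tile
        prob = np.where(inst > 0, 0.999, 0.001)
        refined = postprocess.crf_refine(tile, prob)
        assert refined.shape == prob.shape
        assert refined.min() >= 0.0 and refined.max() <= 1.0
        agreement = ((refined >= 0.5) == (prob >= 0.5)).mean()
        assert agreement > 0.999

    def test_salt_and_pepper_denoised(self):
        rng = np.random.default_rng(0)
        tile = np.full((60, 60, 3), 150, dtype=np.uint8)
        prob = np.full((60, 60), 0.1)
        prob[15:45, 15:45] = 0.9
        noisy = prob.copy()
        flips = rng.random(prob.shape) < 0.05
        noisy[flips] = 1.0 - noisy[flips]
        n_before = ndimage.label(noisy >= 0.5)[1]
        refined = postprocess.crf_refine(tile, noisy)
        n_after = ndimage.label(refined >= 0.5)[1]
        assert n_after < n_before

    def test_shape_guard(self):
        from glandseg.errors import ShapeError
        with pytest.raises(ShapeError):
            postprocess.crf_refine(np.zeros((4, 4, 3)), np.zeros((5, 5)))


def test_segment_end_to_end_on_ground_truth(small_tile):
    """Full post-processing chain (including CRF) on oracle probability maps
    recovers the generator's glands."""
    tile, inst = small_tile
    pair = masks.gland_targets(inst)
    maps = ProbabilityMaps(pair.object_mask.astype(float),
                           pair.contour_mask.astype(float))
    cfg = postprocess.PostprocessConfig(min_area=50)
    seg = postprocess.segment(maps, "gland", tile=tile, cfg=cfg)
    assert metrics.dice_coefficient(inst > 0, seg > 0) > 0.97
    assert seg.max() == inst.max()
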