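"""Loss closed forms, augmentation consistency, normalization statistics,
scheduler contract, and seeded smoke training."""

import dataclasses

import numpy as np
import pytest

from glandseg import masks, synth, train
from glandseg import model as M
from glandseg.errors import DataError, DegenerateStatsError, ShapeError
from glandseg.model import ProbabilityMaps
from glandseg.nn import Adam, ReduceLROnPlateau
from glandseg.nn.tensor import Parameter


def _pair(obj, cnt):
    return masks.TargetPair(object_mask=obj.astype(np.uint8),
                            contour_mask=cnt.astype(np.uint8),
                            approach="gland")


class TestCombinedLoss:
    def test_perfect_prediction_is_near_zero(self):
        t = np.zeros((8, 8))
        t[2:5, 2:5] = 1
        pred = ProbabilityMaps(object_prob=t.copy(), contour_prob=t.copy())
        loss = train.combined_loss(pred, _pair(t, t), weights_norm=0.0,
                                   cfg=train.LossConfig(weight_decay=0.0))
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_gives_ln2(self):
        rng = np.random.default_rng(0)
        obj = rng.random((8, 8)) > 0.5
        cnt = rng.random((8, 8)) > 0.8
        pred = ProbabilityMaps(object_prob=np.full((8, 8), 0.5),
                               contour_prob=np.full((8, 8), 0.5))
        loss = train.combined_loss(pred, _pair(obj, cnt), 0.0,
                                   train.LossConfig(alpha=0.5, weight_decay=0.0))
        assert loss == pytest.approx(np.log(2.0), abs=1e-6)

    def test_alpha_one_ignores_contour(self):
        obj = np.zeros((4, 4))
        good = ProbabilityMaps(object_prob=obj.copy(),
                               contour_prob=np.full((4, 4), 0.5))
        bad = ProbabilityMaps(object_prob=obj.copy(),
                              contour_prob=np.full((4, 4), 0.9))
        cfg = train.LossConfig(alpha=1.0, weight_decay=0.0)
        pair = _pair(obj, np.zeros((4, 4)))
        assert (train.combined_loss(good, pair, 0.0, cfg)
                == train.combined_loss(bad, pair, 0.0, cfg))

    def test_weight_decay_term(self):
        obj = np.zeros((4, 4))
        pred = ProbabilityMaps(object_prob=obj.copy(), contour_prob=obj.copy())
        pair = _pair(obj, obj)
        base = train.combined_loss(pred, pair, 0.0,
                                   train.LossConfig(weight_decay=1e-4))
        with_norm = train.combined_loss(pred, pair, 10.0,
                                        train.LossConfig(weight_decay=1e-4))
        assert with_norm - base == pytest.approx(1e-3)

    def test_shape_mismatch_rejected(self):
        pred = ProbabilityMaps(object_prob=np.zeros((4, 4)),
                               contour_prob=np.zeros((4, 4)))
        with pytest.raises(ShapeError):
            train.combined_loss(pred, _pair(np.zeros((5, 5)), np.zeros((5, 5))))


class TestAugmentation:
    @pytest.fixture()
    def sample(self, small_tile):
        tile, inst = small_tile
        return tile, masks.gland_targets(inst)

    def test_identity_draw_unchanged(self, sample):
        tile, pair = sample
        img, out = train.augment_pair(tile, pair, seed=0,
                                      params=train.IDENTITY_AUGMENT)
        assert np.allclose(img, tile)
        assert np.array_equal(out.object_mask, pair.object_mask)

    def test_flip_is_involution(self, sample):
        tile, pair = sample
        flips_only = train.AugmentParams(p_flip=1.0, p_rotate=0, p_elastic=0,
                                         p_perspective=0, p_noise=0)
        img1, out1 = train.augment_pair(tile, pair, seed=3, params=flips_only)
        img2, out2 = train.augment_pair(img1, out1, seed=99, params=flips_only)
        assert np.allclose(img2, tile)
        assert np.array_equal(out2.object_mask, pair.object_mask)

    def test_seed_determinism(self, sample):
        tile, pair = sample
        a = train.augment_pair(tile, pair, seed=7)
        b = train.augment_pair(tile, pair, seed=7)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1].object_mask, b[1].object_mask)

    def test_joint_transform_consistency(self, sample):
        """Image and masks share one spatial transform: a mask passed through
        both target slots transforms identically, and a mask painted into an
        image channel lands on the transformed mask."""
        tile, pair = sample
        m = pair.object_mask
        _, both = train.augment_pair(tile, masks.TargetPair(m, m, "gland"),
                                     seed=11)
        assert np.array_equal(both.object_mask, both.contour_mask)

        painted = np.repeat((m * 255)[:, :, None], 3, axis=2).astype(float)
        no_noise = train.AugmentParams(p_noise=0.0)
        img, out = train.augment_pair(painted, pair, seed=11, params=no_noise)
        from glandseg.metrics import dice_coefficient
        assert dice_coefficient(img[..., 0] > 127, out.object_mask) > 0.98

    def test_masks_stay_binary(self, sample):
        tile, pair = sample
        for seed in range(5):
            _, out = train.augment_pair(tile, pair, seed=seed)
            assert set(np.unique(out.object_mask)) <= {0, 1}
            assert set(np.unique(out.contour_mask)) <= {0, 1}


class TestNormalizationStats:
    def test_constant_tile_degenerate(self):
        with pytest.raises(DegenerateStatsError):
            train.compute_normalization_stats([np.full((4, 4, 3), 100.0)])

    def test_two_tile_population_stats(self):
        stats = train.compute_normalization_stats(
            [np.full((2, 2, 3), 0.0), np.full((2, 2, 3), 200.0)])
        assert np.allclose(stats.mean, 100.0)
        assert np.allclose(stats.sd, 100.0)

    def test_standardization_fixed_point(self, small_tile):
        tile, _ = small_tile
        stats = train.compute_normalization_stats([tile])
        z = train.standardize(tile, stats)
        assert np.allclose(z.reshape(-1, 3).mean(axis=0), 0.0, atol=1e-9)
        assert np.allclose(z.reshape(-1, 3).std(axis=0), 1.0, atol=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            train.compute_normalization_stats([])


class TestScheduler:
    def test_halves_after_exactly_five_bad_epochs(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=5)
        sched.step(1.0)  # sets the best
        for i in range(4):
            assert not sched.step(1.0)
            assert opt.lr == 1e-3
        assert sched.step(1.0)  # 5th non-improving epoch
        assert opt.lr == pytest.approx(5e-4)

    def test_improvement_resets_counter(self):
        opt = Adam([Parameter(np.zeros(1))], lr=1e-3)
        sched = ReduceLROnPlateau(opt, factor=0.5, patience=5)
        losses = [1.0, 1.0, 1.0, 0.5, 1.0, 1.0, 1.0, 1.0]
        for loss in losses:
            sched.step(loss)
        assert opt.lr == 1e-3  # never 5 consecutive bad epochs


class TestGradientSanity:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_twenty_steps_reduce_loss(self, seed):
        rng = np.random.default_rng(seed)
        cfg = M.ModelConfig(block_layers=(1, 1, 1, 1), growth_rate=4,
                            input_size=32, decoder_channels=(8, 8, 8, 8, 8),
                            seed=seed)
        net = M.build_dense_unet(cfg)
        x = rng.standard_normal((2, 3, 32, 32)).astype(np.float32)
        obj = (rng.random((2, 1, 32, 32)) > 0.5).astype(np.float32)
        cnt = (rng.random((2, 1, 32, 32)) > 0.8).astype(np.float32)
        opt = Adam(list(net.parameters()), lr=1e-3)
        losses = []
        for _ in range(21):
            opt.zero_grad()
            loss = train._forward_loss(net, x, obj, cnt, alpha=0.5)
            losses.append(float(loss.data))
            loss.backward()
            opt.step()
        assert losses[20] < losses[0]


class TestSplit:
    def _manifest(self):
        import pandas as pd
        return pd.DataFrame({
            "image": [f"t{i}.png" for i in range(10)],
            "annotation": [f"a{i}.png" for i in range(10)],
            "split": [""] * 10,
            "morphology": ["benign"] * 5 + ["malignant"] * 5,
        })

    def test_deterministic(self):
        m = self._manifest()
        t1, v1 = train.split_manifest(m, 0.2, seed=3)
        t2, v2 = train.split_manifest(m, 0.2, seed=3)
        assert np.array_equal(t1, t2) and np.array_equal(v1, v2)

    def test_stratified_on_morphology(self):
        m = self._manifest()
        _, val = train.split_manifest(m, 0.2, seed=3)
        morphs = m.loc[val, "morphology"].tolist()
        assert morphs.count("benign") == 1 and morphs.count("malignant") == 1


class TestSmokeTraining:
    def test_validation_loss_improves(self, tmp_path):
        params = synth.SynthParams(tile_size=64, n_glands=2,
                                   gland_radius_range=(8, 14), seed=21)
        manifest = synth.generate_dataset(params, 20, tmp_path)
        cfg = M.ModelConfig(block_layers=(2, 2, 2, 2), growth_rate=8,
                            input_size=64, decoder_channels=(16, 16, 8, 8, 8))
        tcfg = train.TrainConfig(epochs=5, steps_per_epoch=10, seed=0)
        result = train.train_model(manifest, "gland", cfg, tcfg,
                                   log_csv=tmp_path / "log.csv")
        hist = result.history
        assert len(hist) == 5
        assert hist["val_loss"].iloc[-1] < hist["val_loss"].iloc[0]
        assert (tmp_path / "log.csv").exists()
        assert result.best_epoch >= 1

    def test_empty_manifest_rejected(self):
        import pandas as pd
        with pytest.raises(DataError):
            train.train_model(pd.DataFrame(), "gland")
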