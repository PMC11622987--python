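import numpy as np
import pytest

from nganet._autodiff import Tensor
from nganet.classifier import (RolloutMap, ViT, ViTConfig, gradient_rollout,
                               patchify, top_pairs, train_two_phase)


@pytest.fixture(scope="module")
def toy_separable():
    """Two classes of 12x12x1 'pair images' separated by one hot block."""
    rng = np.random.default_rng(0)
    images, labels = [], []
    for i in range(20):
        img = rng.random((12, 12, 1)) * 0.1
        lab = i % 2
        if lab == 1:
            img[2:4, 6:8, 0] += 2.0
            img[6:8, 2:4, 0] += 2.0
        images.append(img)
        labels.append(lab)
    return np.stack(images), np.array(labels)


class TestPatchify:
    def test_pad_120_patch_10_gives_144(self):
        cfg = ViTConfig(patch_size=10, pad_to=120, classes=2)
        patches = patchify(np.zeros((116, 116, 3)), cfg)
        assert patches.shape == (144, 10 * 10 * 3)

    def test_single_patch(self):
        cfg = ViTConfig(patch_size=12, pad_to=12, classes=2)
        assert patchify(np.ones((12, 12, 1)), cfg).shape == (1, 144)

    def test_padding_contributes_zero(self, rng):
        cfg = ViTConfig(patch_size=10, pad_to=120, classes=2)
        img = rng.random((116, 116, 3))
        patches = patchify(img, cfg)
        # the last patch row/col contains the zero-padded strip
        assert patches.sum() == pytest.approx(img.sum())

    def test_row_major_patch_order(self):
        cfg = ViTConfig(patch_size=2, pad_to=4, classes=2)
        img = np.arange(16.0).reshape(4, 4, 1)
        patches = patchify(img, cfg)
        np.testing.assert_array_equal(patches[0], [0, 1, 4, 5])
        np.testing.assert_array_equal(patches[1], [2, 3, 6, 7])


class TestAttention:
    def test_softmax_rows_sum_to_one(self, rng):
        cfg = ViTConfig(patch_size=4, embed_dim=16, heads=2, depth=2,
                        mlp_dim=32, classes=2, seed=0)
        imgs = rng.random((2, 12, 12, 1))
        patches = np.stack([patchify(im, cfg) for im in imgs])
        model = ViT(cfg, patch_dim=patches.shape[-1], n_patches=patches.shape[1])
        model.forward(patches)
        for attn in model.attentions:
            sums = attn.data.sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestTrainTwoPhase:
    def test_separable_toy_reaches_full_training_accuracy(self, toy_separable):
        images, labels = toy_separable
        cfg = ViTConfig(patch_size=4, embed_dim=16, heads=2, depth=2,
                        mlp_dim=32, classes=2, seed=0)
        model, _, _, logs = train_two_phase({"images": images, "labels": labels},
                                            cfg, vit_epochs=50, vit_lr=3e-3, seed=0)
        assert logs["phase2_epochs"] == 50
        preds = model.predict(images)
        assert (preds == labels).mean() == 1.0
        # loss broadly decreases on a separable set
        assert logs["vit_loss"][-1] < logs["vit_loss"][0]

    def test_fixed_seed_reproducible(self, toy_separable):
        images, labels = toy_separable
        cfg = ViTConfig(patch_size=4, embed_dim=16, heads=2, depth=1,
                        mlp_dim=32, classes=2, seed=3)
        _, _, _, l1 = train_two_phase({"images": images, "labels": labels},
                                      cfg, vit_epochs=3, vit_lr=1e-3, seed=3)
        _, _, _, l2 = train_two_phase({"images": images, "labels": labels},
                                      cfg, vit_epochs=3, vit_lr=1e-3, seed=3)
        assert l1["vit_loss"] == l2["vit_loss"]

    def test_epoch_counts_logged(self, toy_separable):
        images, labels = toy_separable
        cfg = ViTConfig(patch_size=4, embed_dim=8, heads=2, depth=1,
                        mlp_dim=16, classes=2, seed=0)
        _, _, _, logs = train_two_phase({"images": images, "labels": labels},
                                        cfg, vit_epochs=2, seed=0)
        assert logs["phase2_epochs"] == 2
        assert len(logs["vit_loss"]) == 2

    def test_too_few_samples_rejected(self):
        cfg = ViTConfig(patch_size=4, classes=2)
        with pytest.raises(ValueError, match="batch_size"):
            train_two_phase({"images": np.zeros((2, 8, 8, 1)),
                             "labels": np.array([0, 1])}, cfg, batch_size=5)


class TestPerPairNets:
    def test_per_pair_configuration(self, rng):
        """shared_net=False trains one association net per region pair."""
        n, k, d = 12, 3, 16
        feats = [rng.standard_normal((n, k, d))]
        proxies = rng.random((n, 3))  # k=3 -> 3 pairs
        labels = np.array([0, 1] * 6)
        cfg = ViTConfig(patch_size=3, embed_dim=8, heads=2, depth=1,
                        mlp_dim=16, classes=2, seed=0)
        ds = {"features": feats, "proxy_targets": proxies, "labels": labels}
        model, ra_nets, images, _ = train_two_phase(
            ds, cfg, ra_epochs=1, vit_epochs=1, batch_size=4,
            shared_net=False, seed=0)
        assert isinstance(ra_nets[0], list)
        assert len(ra_nets[0]) == 3
        assert images.shape == (n, k, k, 1)

    def test_score_all_pairs_paths_agree_on_shapes(self, rng):
        from nganet.regional_association import (RANet, enumerate_pairs,
                                                 score_all_pairs)

        feat = rng.standard_normal((5, 4, 16))
        pairs = enumerate_pairs(4)
        shared = score_all_pairs(RANet(in_dim=16, seed=0), feat, pairs)
        per_pair = score_all_pairs([RANet(in_dim=16, seed=i)
                                    for i in range(len(pairs))], feat, pairs)
        assert shared.shape == per_pair.shape == (5, 6)
        assert np.all((shared >= 0) & (shared <= 1))
        assert np.all((per_pair >= 0) & (per_pair <= 1))


class TestGradientRollout:
    def _trained_toy(self, toy_separable):
        images, labels = toy_separable
        cfg = ViTConfig(patch_size=4, embed_dim=16, heads=2, depth=2,
                        mlp_dim=32, classes=2, seed=0)
        model, _, _, _ = train_two_phase({"images": images, "labels": labels},
                                         cfg, vit_epochs=40, vit_lr=3e-3, seed=0)
        return model, images, labels

    def test_normalized_nonnegative(self, toy_separable):
        model, images, _ = self._trained_toy(toy_separable)
        rm = gradient_rollout(model, images[1], target_class=1)
        assert rm.grid.min() >= 0.0
        assert rm.grid.max() == pytest.approx(1.0)
        assert rm.grid.shape == (12, 12)

    def test_class_index_out_of_range(self, toy_separable):
        model, images, _ = self._trained_toy(toy_separable)
        with pytest.raises(ValueError):
            gradient_rollout(model, images[0], target_class=5)

    def test_identity_attention_uniform(self, rng):
        """With every attention forced to identity the rollout is uniform."""
        cfg = ViTConfig(patch_size=4, embed_dim=8, heads=2, depth=2,
                        mlp_dim=16, classes=2, seed=0)
        img = rng.random((8, 8, 1))
        patches = patchify(img, cfg)[None]
        model = ViT(cfg, patch_dim=patches.shape[-1], n_patches=patches.shape[1])
        logits = model.forward(patches)
        T = patches.shape[1] + 1
        eye = np.broadcast_to(np.eye(T), (1, cfg.heads, T, T)).copy()
        for attn in model.attentions:
            attn.data = eye.copy()
            attn.grad = np.ones_like(eye)  # uniform positive gradient
        rollout = np.eye(T)
        for attn in model.attentions:
            a = attn.data[0]
            g = attn.grad[0]
            fused = np.maximum(a * g, 0).mean(axis=0) + np.eye(T)
            fused /= fused.sum(axis=1, keepdims=True)
            rollout = fused @ rollout
        sal = rollout[0, 1:]
        np.testing.assert_allclose(sal, sal[0])

    def test_one_layer_rollout_equals_fused_attention(self, rng):
        """Oracle: for depth 1 the rollout map equals the residual-adjusted
        gradient-fused attention's class-token row directly."""
        cfg = ViTConfig(patch_size=4, embed_dim=8, heads=2, depth=1,
                        mlp_dim=16, classes=2, seed=1)
        img = rng.random((8, 8, 1))
        patches = patchify(img, cfg)[None]
        model = ViT(cfg, patch_dim=patches.shape[-1], n_patches=patches.shape[1])
        rm = gradient_rollout(model, img, target_class=0)

        logits = model.forward(patches)
        seed_grad = np.zeros(logits.data.shape)
        seed_grad[0, 0] = 1.0
        logits.backward(seed_grad)
        attn = model.attentions[0]
        T = patches.shape[1] + 1
        fused = np.maximum(attn.data[0] * attn.grad[0], 0).mean(axis=0) + np.eye(T)
        fused /= fused.sum(axis=1, keepdims=True)
        expected = fused[0, 1:].reshape(rm.patch_grid.shape)
        np.testing.assert_allclose(rm.patch_grid, expected, atol=1e-12)

    def test_ablation_does_not_increase_saliency(self, toy_separable):
        """Zeroing the informative cells does not raise their raw (pre-
        normalization) saliency for the predicted class, on average over 10
        ablation comparisons."""
        model, images, labels = self._trained_toy(toy_separable)
        idx = [i for i, l in enumerate(labels) if l == 1][:10]
        deltas = []
        for i in idx:
            base = gradient_rollout(model, images[i], 1).patch_grid[0, 1]
            ablated = images[i].copy()
            ablated[2:4, 6:8] = 0.0
            ablated[6:8, 2:4] = 0.0
            abl = gradient_rollout(model, ablated, 1).patch_grid[0, 1]
            deltas.append(abl - base)
        assert np.mean(deltas) <= 1e-9


class TestTopPairs:
    def test_single_hot_cell_first(self):
        grid = np.zeros((6, 6))
        grid[1, 4] = grid[4, 1] = 1.0
        rm = RolloutMap(grid=grid, patch_grid=None, target_class=0)
        ranked = top_pairs(rm, 3, names={2: "hippocampus", 5: "thalamus"})
        pair, ni, nj, s = ranked[0]
        assert (pair.i, pair.j) == (2, 5)
        assert (ni, nj) == ("hippocampus", "thalamus")
        assert s == pytest.approx(1.0)

    def test_tie_break_lexicographic(self):
        rm = RolloutMap(grid=np.ones((4, 4)), patch_grid=None, target_class=0)
        ranked = top_pairs(rm, 3)
        assert [(p.i, p.j) for p, *_ in ranked] == [(1, 2), (1, 3), (1, 4)]

    def test_n_zero_empty(self):
        rm = RolloutMap(grid=np.ones((3, 3)), patch_grid=None, target_class=0)
        assert top_pairs(rm, 0) == []

    def test_clamp_with_warning(self):
        rm = RolloutMap(grid=np.ones((3, 3)), patch_grid=None, target_class=0)
        with pytest.warns(UserWarning, match="clamp"):
            ranked = top_pairs(rm, 99)
        assert len(ranked) == 3
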