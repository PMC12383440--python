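import dataclasses

import numpy as np
import pytest

from modfuse import harness, phantom, preprocess
from modfuse.metrics import dice_score, total_loss_and_grad_from_logits
from modfuse.model import (FusionModel, ModelConfig, ffb_apply, ffb_excite,
                           ffb_fuse, ffb_squeeze)


@pytest.fixture
def tiny_cfg():
    return ModelConfig(encoder_channels=4, se_reduction=4, decoder_channels=6,
                       input_size=16, n_modalities=3)


class TestFFBOracles:
    def test_squeeze_constant_and_half_channels(self):
        m = np.zeros((2, 4, 4))
        m[0] = 3.7
        m[1, :, :2] = 1.0  # half zeros, half ones
        z = ffb_squeeze(m)
        assert z[0] == pytest.approx(3.7)
        assert z[1] == pytest.approx(0.5)

    def test_squeeze_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(0)
        m = rng.normal(size=(8, 5, 7))
        z = ffb_squeeze(m)
        for k in range(8):
            acc = 0.0
            for h in range(5):
                for w in range(7):
                    acc += m[k, h, w]
            assert abs(z[k] - acc / 35) < 1e-6

    def test_excite_zero_weights_give_half(self):
        z = np.random.default_rng(1).normal(size=6)
        s = ffb_excite(z, np.zeros((3, 6)), np.zeros(3), np.zeros((6, 3)), np.zeros(6))
        assert np.allclose(s, 0.5)

    def test_excite_outputs_strictly_in_unit_interval(self):
        rng = np.random.default_rng(2)
        s = ffb_excite(rng.normal(size=6) * 10, rng.normal(size=(3, 6)),
                       rng.normal(size=3), rng.normal(size=(6, 3)), rng.normal(size=6))
        assert np.all(s > 0) and np.all(s < 1)

    def test_excite_matches_matrix_vector_loop_oracle(self):
        rng = np.random.default_rng(3)
        c2, r = 6, 2
        z = rng.normal(size=c2)
        W1, b1 = rng.normal(size=(c2 // r, c2)), rng.normal(size=c2 // r)
        W2, b2 = rng.normal(size=(c2, c2 // r)), rng.normal(size=c2)
        s = ffb_excite(z, W1, b1, W2, b2)
        h = np.zeros(c2 // r)
        for i in range(c2 // r):
            acc = b1[i]
            for j in range(c2):
                acc += W1[i, j] * z[j]
            h[i] = max(acc, 0.0)
        for k in range(c2):
            acc = b2[k]
            for i in range(c2 // r):
                acc += W2[k, i] * h[i]
            assert abs(s[k] - 1 / (1 + np.exp(-acc))) < 1e-6

    def test_apply_identity_zero_and_random(self):
        rng = np.random.default_rng(4)
        m = rng.normal(size=(5, 3, 3))
        assert np.array_equal(ffb_apply(m, np.ones(5)), m)
        assert np.all(ffb_apply(m, np.zeros(5)) == 0)
        s = rng.uniform(size=5)
        out = ffb_apply(m, s)
        for k in range(5):
            assert np.allclose(out[k], s[k] * m[k], atol=1e-7)

    def test_fuse_residual_algebra(self):
        rng = np.random.default_rng(5)
        concat = rng.normal(size=(1, 4, 3, 3))
        proj_W = rng.normal(size=(2, 4, 1, 1))
        proj_b = rng.normal(size=2)
        # s == 1 => modulated == concat => residual input is 2*concat
        out = ffb_fuse(concat, concat, proj_W, proj_b)
        doubled = ffb_fuse(2 * concat, 2 * concat, proj_W, proj_b)
        lin = np.einsum("dc,bchw->bdhw", proj_W[:, :, 0, 0], 2 * concat) + proj_b[None, :, None, None]
        assert np.allclose(out, lin, atol=1e-10)
        # zero map: output equals the projection bias pattern
        zero = ffb_fuse(np.zeros_like(concat), np.zeros_like(concat), proj_W, proj_b)
        assert np.allclose(zero, np.broadcast_to(proj_b[None, :, None, None], zero.shape))
        assert doubled.shape == out.shape


class TestEncoder:
    def test_identical_modalities_give_identical_maps(self, tiny_cfg):
        model = FusionModel(tiny_cfg, seed=0)
        img = np.random.default_rng(0).uniform(size=(1, 1, 3, 16, 16))
        images = np.repeat(img, 3, axis=1)
        fset, _ = model.encode_modalities(images)
        assert np.array_equal(fset.maps[0], fset.maps[1])
        assert np.array_equal(fset.maps[1], fset.maps[2])

    def test_spatial_stride_reduction(self):
        cfg = ModelConfig(encoder_channels=8, se_reduction=4, input_size=64)
        model = FusionModel(cfg, seed=0)
        images = np.zeros((1, 4, 3, 64, 64))
        fset, _ = model.encode_modalities(images)
        assert fset.maps[0].shape == (1, 8, 16, 16)

    def test_frozen_encoder_unchanged_by_training(self, cohort10):
        cfg = harness.desk_config(epochs=1)
        frozen_model_cfg = dataclasses.replace(cfg.model,
                                               trainable_parts=frozenset({"ffb", "decoder"}))
        cfg = dataclasses.replace(cfg, model=frozen_model_cfg, epochs=1)
        ds = preprocess.build_slice_dataset(cohort10[:2], "WT", cfg.preprocess)
        before = FusionModel(cfg.model, seed=cfg.seed).params
        result = harness.train(ds[:16], cfg)
        for k in result.model.params:
            if k.startswith("enc."):
                assert np.array_equal(result.model.params[k], before[k])
            elif k.startswith("ffb.") or k.startswith("dec."):
                assert not np.array_equal(result.model.params[k], before[k])


class TestForward:
    def test_logit_map_at_input_resolution(self, tiny_cfg):
        model = FusionModel(tiny_cfg, seed=0)
        images = np.random.default_rng(0).uniform(size=(2, 3, 3, 16, 16))
        bboxes = np.array([[1, 1, 10, 10], [0, 0, 15, 15]], dtype=float)
        logits, _ = model.forward(images, bboxes)
        assert logits.shape == (2, 16, 16)

    def test_swapping_identical_modalities_preserves_logits(self, tiny_cfg):
        model = FusionModel(tiny_cfg, seed=0)
        rng = np.random.default_rng(1)
        img = rng.uniform(size=(1, 1, 3, 16, 16))
        other = rng.uniform(size=(1, 1, 3, 16, 16))
        images = np.concatenate([img, img, other], axis=1)
        swapped = np.concatenate([img, img, other], axis=1)[:, [1, 0, 2]]
        bb = np.array([[2, 2, 12, 12]], dtype=float)
        a, _ = model.forward(images, bb)
        b, _ = model.forward(swapped, bb)
        assert np.array_equal(a, b)

    def test_untrained_model_segments_poorly(self, trained_wt):
        _, _, test_recs = trained_wt
        cfg = harness.desk_config().model
        fresh = FusionModel(cfg, seed=123)
        rec = test_recs[0]
        pred = fresh.predict_mask(rec.modality_images[None].astype(float),
                                  np.array([rec.bbox], dtype=float))[0]
        assert dice_score(rec.gt_mask, pred) < 0.5

    def test_full_model_gradients_match_finite_differences(self, tiny_cfg):
        model = FusionModel(tiny_cfg, seed=0)
        rng = np.random.default_rng(2)
        x = rng.uniform(size=(2, 3, 3, 16, 16))
        bb = np.array([[2, 3, 10, 12], [1, 1, 14, 14]], dtype=float)
        gt = (rng.uniform(size=(2, 16, 16)) > 0.5).astype(float)

        logits, cache = model.forward(x, bb)
        _, dlogits = total_loss_and_grad_from_logits(logits, gt)
        grads = model.backward(dlogits, cache)

        def loss():
            lg, _ = model.forward(x, bb)
            return total_loss_and_grad_from_logits(lg, gt)[0].total

        check_rng = np.random.default_rng(3)
        for name, p in model.params.items():
            g = grads[name]
            assert np.all(np.isfinite(g))
            for _ in range(3):
                idx = tuple(check_rng.integers(0, s) for s in p.shape)
                eps, orig = 1e-6, p[idx]
                p[idx] = orig + eps
                lp = loss()
                p[idx] = orig - eps
                lm = loss()
                p[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert abs(num - g[idx]) <= 1e-4 * max(1.0, abs(num) + abs(g[idx])), name


def test_single_modality_model_learns(small_spec):
    """With N=1 the full FFB path still runs and a FLAIR-only model reaches a
    high training Dice — the single-modality degradation case."""
    spec = dataclasses.replace(small_spec, n_modalities=1,
                               contrast_matrix=np.array([[0.8, 0.0, 0.0]]),
                               modality_names=("FLAIR",))
    cohort = phantom.generate_cohort(spec, 4)
    cfg = harness.desk_config(epochs=4)
    model_cfg = dataclasses.replace(cfg.model, n_modalities=1, se_reduction=4)
    cfg = dataclasses.replace(cfg, model=model_cfg)
    ds = preprocess.build_slice_dataset(cohort, "WT", cfg.preprocess)
    ds = [r for r in ds if r.z_index % 2 == 0]
    result = harness.train(ds, cfg, ("FLAIR",))
    report = harness.evaluate(result.model, ds, cfg.policy, modality_names=("FLAIR",))
    assert report.mean_dice > 0.8


class TestConfigAndPersistence:
    def test_foundation_frozen_forbids_trainable_encoder(self):
        with pytest.raises(ValueError):
            ModelConfig(encoder_kind="foundation_frozen",
                        trainable_parts=frozenset({"encoder"}))

    def test_foundation_weights_missing_is_actionable(self):
        cfg = ModelConfig(encoder_kind="foundation_frozen",
                          trainable_parts=frozenset({"ffb", "decoder"}),
                          foundation_checkpoint="/nonexistent/medsam.pth")
        with pytest.raises(FileNotFoundError, match="/nonexistent/medsam.pth"):
            FusionModel(cfg)

    def test_checkpoint_roundtrip(self, tiny_cfg, tmp_path):
        model = FusionModel(tiny_cfg, seed=5)
        path = str(tmp_path / "model.npz")
        model.save(path)
        back = FusionModel.load(path)
        assert back.config == tiny_cfg
        for k in model.params:
            assert np.array_equal(model.params[k], back.params[k])

    def test_bottleneck_width_validated(self):
        with pytest.raises(ValueError):
            ModelConfig(n_modalities=1, encoder_channels=4, se_reduction=8)
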