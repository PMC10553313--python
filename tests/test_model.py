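"""Cascade model: backbone shapes, heads, APN squashing, plumbing."""

import numpy as np
import pytest

from pestnet.attention import AttentionBox, CropConfig, attention_crop_tensors
from pestnet.autodiff import Tensor
from pestnet.model import BackboneConfig, CascadeModel, soft_vote
from pestnet.training import images_to_array


@pytest.fixture
def images(small_dataset):
    x, _ = images_to_array(small_dataset[:4])
    return x


class TestBackbone:
    def test_stage_spatial_sizes_halve(self, small_model, images):
        feats = small_model.backbone_forward(Tensor(images), 0)
        sizes = [f.shape[2] for f in feats]
        assert sizes == [16, 8, 4, 2, 1]

    def test_wrong_input_size_raises(self, small_model):
        with pytest.raises(ValueError, match="spatial size"):
            small_model.backbone_forward(
                Tensor(np.zeros((1, 3, 16, 16), np.float32)), 0)

    def test_eval_determinism(self, small_model, images):
        a = small_model.cascade_forward(images)
        b = small_model.cascade_forward(images)
        assert np.array_equal(a.fused_prob, b.fused_prob)
        for sa, sb in zip(a.scales, b.scales):
            assert np.array_equal(sa.boxes, sb.boxes)

    def test_zero_conv_params_give_spatially_constant_stages(self, images):
        cfg = BackboneConfig(channels=(4, 8, 8, 8, 8), input_size=32,
                             n_classes=3)
        model = CascadeModel(cfg, seed=0)
        for i in range(5):
            model.params[f"s0.conv{i}.w"].data[:] = 0.0
        feats = model.backbone_forward(Tensor(images), 0)
        for f in feats:
            flat = f.data.reshape(f.shape[0], f.shape[1], -1)
            assert np.allclose(flat, flat[:, :, :1], atol=1e-7)

    def test_five_stages_required(self):
        with pytest.raises(ValueError):
            BackboneConfig(channels=(4, 8, 8, 8))


class TestPoolHeads:
    def test_zero_parameters_give_uniform(self, images):
        cfg = BackboneConfig(channels=(4, 8, 8, 8, 8), input_size=32,
                             n_classes=3)
        model = CascadeModel(cfg, seed=0)
        model.params["s0.head4.w"].data[:] = 0.0
        model.params["s0.head4.b"].data[:] = 0.0
        feats = model.backbone_forward(Tensor(images), 0)
        p = model.pool_head_predict(feats[4], 0, 4).data
        assert np.allclose(p, 1.0 / 3, atol=1e-6)

    def test_simplex_for_random_parameters(self, small_model, images, rng):
        feats = small_model.backbone_forward(Tensor(images), 0)
        for _ in range(20):
            small_model.params["s0.head2.w"].data = rng.normal(
                0, 1, small_model.params["s0.head2.w"].shape).astype(np.float32)
            p = small_model.pool_head_predict(feats[2], 0, 2).data
            assert (p > 0).all()
            assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_class_permutation_equivariance(self, small_model, images):
        feats = small_model.backbone_forward(Tensor(images), 0)
        p0 = small_model.pool_head_predict(feats[4], 0, 4).data.copy()
        perm = np.array([2, 0, 1])
        w = small_model.params["s0.head4.w"]
        b = small_model.params["s0.head4.b"]
        w.data = w.data[:, perm].copy()
        b.data = b.data[perm].copy()
        p1 = small_model.pool_head_predict(feats[4], 0, 4).data
        assert np.allclose(p1, p0[:, perm], atol=1e-6)


class TestAPN:
    def _boxes(self, model, images):
        feats = model.backbone_forward(Tensor(images), 0)
        tx, ty, tl = model.apn_predict(feats[3], 0)
        return tx.data, ty.data, tl.data

    def test_box_always_valid_for_random_parameters(self, images, rng):
        cfg = BackboneConfig(channels=(4, 8, 8, 8, 8), input_size=32,
                             n_classes=3)
        model = CascadeModel(cfg, seed=0)
        size = cfg.input_size
        ccfg = model.crop_cfg
        for _ in range(20):
            for k in ("apn1.w", "apn1.b", "apn2.w", "apn2.b"):
                t = model.params[f"s0.{k}"]
                t.data = rng.normal(0, 2, t.shape).astype(np.float32)
            tx, ty, tl = self._boxes(model, images)
            assert (tl >= ccfg.min_half_len - 1e-4).all()
            assert (tl <= ccfg.max_half_frac * size + 1e-4).all()
            assert (tx - tl >= -0.5 - 1e-3).all()
            assert (tx + tl <= size - 0.5 + 1e-3).all()
            assert (ty - tl >= -0.5 - 1e-3).all()
            assert (ty + tl <= size - 0.5 + 1e-3).all()

    def test_zero_parameters_center_mid_range(self, images):
        cfg = BackboneConfig(channels=(4, 8, 8, 8, 8), input_size=32,
                             n_classes=3)
        model = CascadeModel(cfg, seed=0)
        for k in ("apn1.w", "apn1.b", "apn2.w", "apn2.b"):
            model.params[f"s0.{k}"].data[:] = 0.0
        tx, ty, tl = self._boxes(model, images)
        size, ccfg = 32, model.crop_cfg
        mid_tl = ccfg.min_half_len + 0.5 * (ccfg.max_half_frac * size
                                            - ccfg.min_half_len)
        assert np.allclose(tx, (size - 1) / 2, atol=1e-5)
        assert np.allclose(ty, (size - 1) / 2, atol=1e-5)
        assert np.allclose(tl, mid_tl, atol=1e-5)

    def test_box_varies_continuously_with_input(self, small_model, images):
        base = images.copy()
        tx0, ty0, tl0 = self._boxes(small_model, base)
        deltas = []
        for eps in (1e-3, 1e-2):
            pert = base + eps * np.ones_like(base)
            tx1, ty1, tl1 = self._boxes(small_model, np.clip(pert, 0, 1))
            deltas.append(np.abs(tx1 - tx0).max() + np.abs(ty1 - ty0).max()
                          + np.abs(tl1 - tl0).max())
        assert deltas[0] < deltas[1] + 1e-6
        assert deltas[0] < 1.0  # small perturbation, small box motion


class TestCascade:
    def test_constant_gray_smoke(self, small_model):
        x = np.full((2, 3, 32, 32), 0.5, np.float32)
        out = small_model.cascade_forward(x)
        assert len(out.scales) == 3
        assert np.allclose(out.fused_prob.sum(axis=1), 1.0, atol=1e-6)
        for s in out.scales:
            for p in s.pool_probs:
                assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
                assert (p >= 0).all()

    def test_scale2_input_is_crop_of_scale1(self, small_model, images):
        """Plumbing identity: the image fed to scale m+1 equals
        crop_and_zoom of scale m's input under scale m's box, bit-exactly."""
        out = small_model.cascade_forward(images)
        for m in range(2):
            b = out.scales[m].boxes
            recomputed = attention_crop_tensors(
                Tensor(out.scale_inputs[m]),
                Tensor(b[:, 0].astype(np.float32)),
                Tensor(b[:, 1].astype(np.float32)),
                Tensor(b[:, 2].astype(np.float32)),
                small_model.crop_cfg).data
            assert np.array_equal(recomputed, out.scale_inputs[m + 1])

    def test_oracle_box_magnifies_patch(self, small_spec, crop_cfg):
        """With the box set to the truth box and tl <= input/4, the next
        scale's input contains the full patch at >= 2x magnification."""
        from pestnet.synthetic import generate_scene

        im = generate_scene(small_spec, 0, np.random.default_rng(3))
        b = im.truth_box  # half length 4-6 <= 32/4
        x = im.pixels.transpose(2, 0, 1)[None].astype(np.float32)
        cfg = CropConfig(steepness=1e4, out_size=32, min_half_len=4.0)
        crop = attention_crop_tensors(
            Tensor(x), Tensor(np.array([b.tx], np.float32)),
            Tensor(np.array([b.ty], np.float32)),
            Tensor(np.array([b.tl], np.float32)), cfg).data[0]
        zoom = cfg.out_size / (2 * b.tl)
        assert zoom >= 2.0
        # center pixel of the crop equals the patch center pixel
        c = cfg.out_size // 2
        orig = im.pixels[int(b.ty), int(b.tx)]
        assert np.abs(crop[:, c, c] - orig).max() < 0.25


class TestSoftVote:
    def test_identical_vectors_pass_through(self, rng):
        p = rng.dirichlet(np.ones(4), 3)
        out = soft_vote([p, p, p], [0.2, 0.5, 0.3])
        assert np.allclose(out, p)

    def test_degenerate_weight_selects_vector(self, rng):
        ps = [rng.dirichlet(np.ones(4), 2) for _ in range(3)]
        out = soft_vote(ps, [1.0, 0.0, 0.0])
        assert np.allclose(out, ps[0])

    def test_hand_computed_combination(self, rng):
        ps = [rng.dirichlet(np.ones(5)) for _ in range(3)]
        w = [0.5, 0.3, 0.2]
        out = soft_vote(ps, w)
        hand = 0.5 * ps[0] + 0.3 * ps[1] + 0.2 * ps[2]
        assert np.abs(out - hand).max() < 1e-12

    def test_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            soft_vote([rng.dirichlet(np.ones(3))], [0.5, 0.5])

    def test_nonsimplex_weights_rejected(self, rng):
        ps = [rng.dirichlet(np.ones(3)) for _ in range(2)]
        with pytest.raises(ValueError):
            soft_vote(ps, [0.9, 0.3])


class TestStateDict:
    def test_roundtrip(self, small_model, images):
        before = small_model.cascade_forward(images).fused_prob
        state = small_model.state_dict()
        for t in small_model.params.values():
            t.data = t.data + 1.0
        small_model.load_state_dict(state)
        after = small_model.cascade_forward(images).fused_prob
        assert np.array_equal(before, after)
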