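"""Encoder and fusion heads: shape contracts, attention behaviour, baselines."""

import numpy as np
import pytest

from actifuse.autodiff import Tensor
from actifuse.model import (BiLstmConfig, FusionConfig, MultimodalNet,
                            ViTConfig, cross_attention_fuse)
from actifuse.nn import BiLstm, VisionTransformer


@pytest.fixture(scope="module")
def tiny_net():
    return MultimodalNet(ViTConfig.tiny(), BiLstmConfig.tiny(),
                         FusionConfig.tiny(), tabular_dim=7, seed=0)


def batch(rng, n=2, size=32):
    return rng.random((n, 5, 3, size, size)), rng.normal(size=(n, 7))


class TestViTEncoder:
    def test_five_frames_give_five_embeddings(self, tiny_net, rng):
        frames, _ = batch(rng)
        emb = tiny_net.encode_images(Tensor(frames))
        assert emb.shape == (2, 5, 64)
        assert np.isfinite(emb.data).all()

    def test_identical_frames_identical_embeddings(self, tiny_net, rng):
        frame = rng.random((1, 3, 32, 32))
        frames = np.repeat(frame[None], 5, axis=1)
        tiny_net.eval()
        emb = tiny_net.encode_images(Tensor(frames)).data
        np.testing.assert_allclose(emb[0, 0], emb[0, 3], atol=1e-6)

    def test_shape_mismatch_reports_expectation(self, tiny_net, rng):
        with pytest.raises(ValueError, match="32"):
            tiny_net.vit(Tensor(rng.random((1, 3, 16, 16))))

    def test_gradient_reaches_patch_projection(self, tiny_net, rng):
        frames, tab = batch(rng)
        tiny_net.train()
        tiny_net.zero_grad()
        logits = tiny_net(Tensor(frames), Tensor(tab))
        logits.sum().backward()
        g = tiny_net.vit.patch_proj.weight.grad
        assert g is not None and np.any(g != 0)

    def test_config_validation(self):
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig(image_size=30, patch_size=8)
        with pytest.raises(ValueError, match="divisible"):
            ViTConfig(embed_dim=100, heads=12)
        with pytest.raises(ValueError, match="weights_path"):
            ViTConfig(pretrained=True)


class TestBiLstm:
    def test_token_dimension_is_twice_hidden(self, rng):
        lstm = BiLstm(16, 128, 2, np.random.default_rng(0))
        x = Tensor(rng.normal(size=(3, 5, 16)))
        tokens, pooled = lstm(x)
        assert tokens.shape == (3, 5, 256)
        assert pooled.shape == (3, 256)

    def test_single_frame_pooled_equals_token(self, rng):
        lstm = BiLstm(8, 12, 1, np.random.default_rng(1))
        x = Tensor(rng.normal(size=(2, 1, 8)))
        tokens, pooled = lstm(x)
        np.testing.assert_allclose(tokens.data[:, 0, :], pooled.data, atol=1e-7)

    def test_direction_sensitivity(self, rng):
        lstm = BiLstm(8, 12, 1, np.random.default_rng(2))
        x = rng.normal(size=(1, 5, 8))
        _, fwd = lstm(Tensor(x))
        _, rev = lstm(Tensor(x[:, ::-1].copy()))
        assert not np.allclose(fwd.data, rev.data, atol=1e-6)

    def test_empty_sequence_rejected(self, rng):
        lstm = BiLstm(8, 12, 1, np.random.default_rng(3))
        with pytest.raises(ValueError, match="empty"):
            lstm(Tensor(np.zeros((2, 0, 8))))


class TestCrossAttention:
    def test_weights_sum_to_one(self, rng):
        q = Tensor(rng.normal(size=(4, 1, 32)))
        k = Tensor(rng.normal(size=(4, 5, 32)))
        v = Tensor(rng.normal(size=(4, 5, 32)))
        fused, attn = cross_attention_fuse(q, k, v, heads=2)
        assert fused.shape == (4, 32)
        w = attn.data
        assert np.all(w >= 0) and np.all(w <= 1)
        np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_single_token_returns_value_exactly(self, rng):
        q = Tensor(rng.normal(size=(3, 1, 32)))
        k = Tensor(rng.normal(size=(3, 1, 32)))
        v = Tensor(rng.normal(size=(3, 1, 32)))
        for heads in (1, 2, 4):
            fused, _ = cross_attention_fuse(q, k, v, heads=heads)
            np.testing.assert_array_equal(fused.data, v.data[:, 0, :])

    def test_identical_tokens_return_value_row(self, rng):
        q = Tensor(rng.normal(size=(2, 1, 16)))
        k = Tensor(np.repeat(rng.normal(size=(2, 1, 16)), 5, axis=1))
        v = Tensor(np.repeat(rng.normal(size=(2, 1, 16)), 5, axis=1))
        fused, _ = cross_attention_fuse(q, k, v, heads=1)
        np.testing.assert_allclose(fused.data, v.data[:, 0, :], atol=1e-6)

    def test_joint_kv_permutation_invariance(self, rng):
        q = Tensor(rng.normal(size=(2, 1, 32)))
        k = rng.normal(size=(2, 5, 32))
        v = rng.normal(size=(2, 5, 32))
        perm = np.random.default_rng(0).permutation(5)
        f1, _ = cross_attention_fuse(q, Tensor(k), Tensor(v), heads=2)
        f2, _ = cross_attention_fuse(q, Tensor(k[:, perm]), Tensor(v[:, perm]), heads=2)
        np.testing.assert_allclose(f1.data, f2.data, atol=1e-6)

    def test_dk_mismatch_is_config_error(self):
        with pytest.raises(ValueError, match="divisible"):
            FusionConfig(d_k=33, heads=2)


class TestFusionBaselines:
    def _net(self, kind, seed=0):
        return MultimodalNet(ViTConfig.tiny(), BiLstmConfig.tiny(),
                             FusionConfig(kind=kind, d_k=32, heads=2), 7, seed=seed)

    def test_simple_concat_contract(self, rng):
        net = self._net("simple_concat")
        net.eval()
        pooled = Tensor(rng.normal(size=(2, 64)))
        tab0 = Tensor(np.zeros((2, 7)))
        out0 = net.fuse(tab0, None, pooled)
        assert out0.shape == (2, 32)
        # zero tabular input -> output depends only on the image part + bias
        out_again = net.fuse(Tensor(np.zeros((2, 7))), None, pooled)
        np.testing.assert_array_equal(out0.data, out_again.data)
        out_tab = net.fuse(Tensor(rng.normal(size=(2, 7))), None, pooled)
        assert not np.allclose(out0.data, out_tab.data)

    def test_weighted_sum_gate(self, rng):
        net = self._net("weighted_sum")
        net.eval()
        tab = Tensor(rng.normal(size=(2, 7)))
        pooled = Tensor(rng.normal(size=(2, 64)))
        # alpha = 0 -> exact 0.5/0.5 mixture
        fused = net.fuse(tab, None, pooled)
        expected = 0.5 * net.proj_tab(tab).data + 0.5 * net.proj_img(pooled).data
        np.testing.assert_allclose(fused.data, expected, atol=1e-6)
        # saturated gate -> tabular projection only
        net.alpha.data = np.array([30.0], dtype=net.alpha.data.dtype)
        fused = net.fuse(tab, None, pooled)
        np.testing.assert_allclose(fused.data, net.proj_tab(tab).data, atol=1e-5)

    def test_weighted_sum_alpha_learns(self, rng):
        net = self._net("weighted_sum")
        net.train()
        frames, tab = batch(rng)
        net.zero_grad()
        net(Tensor(frames), Tensor(tab))[:, 1].sum().backward()
        assert net.alpha.grad is not None and abs(net.alpha.grad[0]) > 0

    def test_dual_stream_mean_of_heads(self, rng):
        net = self._net("dual_stream")
        net.eval()
        frames, tab = batch(rng)
        logits = net(Tensor(frames), Tensor(tab)).data
        # recompute by hand from the two streams
        emb = net.encode_images(Tensor(frames))
        _, pooled = net.lstm(emb)
        expected = 0.5 * (net.tab_head(Tensor(tab)).data + net.img_head(pooled).data)
        np.testing.assert_allclose(logits, expected, atol=1e-6)


class TestClassifierHead:
    def test_probabilities_sum_to_one(self, tiny_net, rng):
        frames, tab = batch(rng, n=4)
        probs = tiny_net.predict_proba(frames, tab)
        assert probs.shape == (4, 2)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_softmax_shift_invariance(self):
        a = Tensor(np.array([[1.0, 3.0]]))
        b = Tensor(np.array([[11.0, 13.0]]))
        np.testing.assert_allclose(a.softmax(axis=-1).data, b.softmax(axis=-1).data,
                                   atol=1e-6)

    def test_eval_forward_deterministic(self, tiny_net, rng):
        frames, tab = batch(rng)
        p1 = tiny_net.predict_proba(frames, tab)
        p2 = tiny_net.predict_proba(frames, tab)
        np.testing.assert_array_equal(p1, p2)

    def test_dropout_only_in_training(self, tiny_net, rng):
        frames, tab = batch(rng)
        tiny_net.train()
        out1 = tiny_net(Tensor(frames), Tensor(tab)).data
        out2 = tiny_net(Tensor(frames), Tensor(tab)).data
        assert not np.array_equal(out1, out2)  # dropout noise
        tiny_net.eval()


class TestSizeContracts:
    def test_study_scale_dimensions_end_to_end(self, rng):
        # study-scale widths: 768-d frame embedding, 256-d BiLSTM token,
        # 128-d fused vector, 2 logits
        net = MultimodalNet(ViTConfig(), BiLstmConfig(),
                            FusionConfig(d_k=128, heads=4), tabular_dim=7, seed=0)
        net.eval()
        frames = rng.random((1, 5, 3, 224, 224)).astype(np.float32)
        tab = rng.normal(size=(1, 7))
        emb = net.encode_images(Tensor(frames))
        assert emb.shape == (1, 5, 768)
        tokens, pooled = net.lstm(emb)
        assert tokens.shape == (1, 5, 256) and pooled.shape == (1, 256)
        fused = net.fuse(Tensor(tab), tokens, pooled)
        assert fused.shape == (1, 128)
        logits = net.classify(fused)
        assert logits.shape == (1, 2)

    def test_single_token_mode_uses_pooled_vector(self, rng):
        net = MultimodalNet(ViTConfig.tiny(), BiLstmConfig.tiny(),
                            FusionConfig(d_k=32, heads=2, single_token=True), 7, seed=0)
        net.eval()
        frames, tab = batch(rng)
        emb = net.encode_images(Tensor(frames))
        tokens, pooled = net.lstm(emb)
        fused = net.fuse(Tensor(tab), tokens, pooled)
        # literal single-vector reading: softmax over one token -> fused = W_v pooled
        np.testing.assert_allclose(fused.data, net.w_v(pooled).data, atol=1e-6)
        assert net.last_attention_.shape[-1] == 1

    def test_lstm_vit_width_mismatch_rejected(self):
        with pytest.raises(ValueError, match="embed_dim"):
            MultimodalNet(ViTConfig.tiny(), BiLstmConfig(input_dim=128, hidden=8, layers=1),
                          FusionConfig.tiny(), 7)
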