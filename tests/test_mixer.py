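import numpy as np
import pytest

from conftest import make_block
from oracles import (channel_mixer_loop, mixer_forward_loop, mlp_rows_loop,
                     token_mixer_loop, tokenize_loop)
from thymixer import nn
from thymixer.errors import ParameterError
from thymixer.mixer import (Backbone, BACKBONE_PLANS, MixerNet, ModelConfig,
                            channel_mixer, classify, extract_features,
                            mixer_forward, mlp_inner, register_backbone,
                            token_mixer, tokenize)


class TestExtractFeatures:
    def test_small_backbone_shape_and_determinism(self):
        bb = Backbone(BACKBONE_PLANS["small"], np.random.default_rng(0))
        patch = np.random.default_rng(1).random((224, 112, 3)).astype(np.float32)
        f1 = extract_features(patch, bb)
        f2 = extract_features(patch.copy(), bb)
        assert f1.shape == (7, 3, 32)
        np.testing.assert_array_equal(f1, f2)

    def test_all_zero_patch_finite(self):
        bb = Backbone(BACKBONE_PLANS["small"], np.random.default_rng(0))
        f = extract_features(np.zeros((224, 112, 3), dtype=np.float32), bb)
        assert np.isfinite(f).all()

    def test_backbone_registry(self):
        register_backbone("nano", ((2,), (2,), (2,), (2,), (4,)))
        cfg = ModelConfig(backbone="nano", channels=8)
        net = MixerNet(cfg, seed=0)
        assert net.backbone.out_channels == 4
        with pytest.raises(ParameterError):
            ModelConfig(backbone="does_not_exist")


class TestTokenize:
    def test_shape_21x256(self):
        proj = nn.Dense(512, 256, rng=np.random.default_rng(0))
        f = np.random.default_rng(1).standard_normal((7, 3, 512))
        assert tokenize(f, proj).shape == (21, 256)

    def test_identity_extended_projection(self):
        proj = nn.Dense(512, 256, rng=np.random.default_rng(0), init="zeros")
        proj.params["W"][:256, :] = np.eye(256, dtype=np.float32)
        f = np.random.default_rng(1).standard_normal((7, 3, 512))
        t = tokenize(f, proj)
        np.testing.assert_allclose(t, f.reshape(21, 512)[:, :256], atol=1e-12)

    def test_matches_loop_oracle(self):
        proj = nn.Dense(512, 256, rng=np.random.default_rng(2))
        f = np.random.default_rng(3).standard_normal((7, 3, 512))
        np.testing.assert_allclose(tokenize(f, proj), tokenize_loop(f, proj),
                                   atol=1e-6)


class TestMlpInner:
    def test_zero_weights_zero_output(self):
        block = make_block(3, 4)
        block.channel_mlp.zero_weights()
        x = np.random.default_rng(0).standard_normal((3, 4))
        assert (mlp_inner(x, block.channel_mlp) == 0).all()

    def test_loop_oracle_s2_c3(self):
        block = make_block(2, 3, seed=5)
        x = np.random.default_rng(6).standard_normal((2, 3))
        np.testing.assert_allclose(mlp_inner(x, block.channel_mlp),
                                   mlp_rows_loop(x, block.channel_mlp),
                                   atol=1e-6)


class TestMixers:
    def test_token_mixer_residual_identity(self):
        block = make_block(3, 2)
        block.token_mlp.zero_weights()
        x = np.random.default_rng(0).standard_normal((3, 2))
        np.testing.assert_array_equal(token_mixer(x, block), x)

    def test_token_mixer_loop_oracle(self):
        block = make_block(3, 2, seed=1)
        x = np.random.default_rng(2).standard_normal((3, 2))
        np.testing.assert_allclose(token_mixer(x, block),
                                   token_mixer_loop(x, block), atol=1e-6)

    def test_channel_mixer_identity_and_oracle(self):
        block = make_block(2, 4, seed=3)
        x = np.random.default_rng(4).standard_normal((2, 4))
        np.testing.assert_allclose(channel_mixer(x, block),
                                   channel_mixer_loop(x, block), atol=1e-6)
        block.channel_mlp.zero_weights()
        np.testing.assert_array_equal(channel_mixer(x, block), x)

    def test_channel_mixer_commutes_with_token_permutation(self):
        block = make_block(5, 3, seed=7)
        x = np.random.default_rng(8).standard_normal((5, 3))
        perm = np.random.default_rng(9).permutation(5)
        np.testing.assert_allclose(channel_mixer(x, block)[perm],
                                   channel_mixer(x[perm], block), atol=1e-12)

    def test_shapes_preserved(self):
        block = make_block(4, 5)
        x = np.random.default_rng(0).standard_normal((4, 5))
        assert token_mixer(x, block).shape == x.shape
        assert channel_mixer(x, block).shape == x.shape

    def test_random_instances_against_oracle(self):
        """50 random small instances, both mixers plus the full stack."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for i in range(50):
            s = int(rng.integers(2, 5))
            c = int(rng.integers(2, 6))
            blocks = [make_block(s, c, seed=100 + i), make_block(s, c, seed=200 + i)]
            x = rng.standard_normal((s, c))
            got = mixer_forward(x, blocks)
            want = mixer_forward_loop(x, blocks)
            worst = max(worst, float(np.abs(got - want).max()))
        assert worst < 1e-5

    def test_two_zero_blocks_are_identity(self):
        blocks = [make_block(4, 3, seed=1), make_block(4, 3, seed=2)]
        for b in blocks:
            b.token_mlp.zero_weights()
            b.channel_mlp.zero_weights()
        x = np.random.default_rng(3).standard_normal((4, 3))
        np.testing.assert_array_equal(mixer_forward(x, blocks), x)

    def test_one_block_equals_composition(self):
        block = make_block(3, 4, seed=4)
        x = np.random.default_rng(5).standard_normal((3, 4))
        np.testing.assert_allclose(mixer_forward(x, [block]),
                                   channel_mixer(token_mixer(x, block), block),
                                   atol=1e-12)


class TestClassify:
    def test_zero_head_uniform(self):
        head = nn.Dense(4, 2, rng=np.random.default_rng(0), init="zeros")
        x = np.random.default_rng(1).standard_normal((5, 4))
        np.testing.assert_allclose(classify(x, head), [0.5, 0.5], atol=1e-12)

    def test_probabilities_sum_to_one(self):
        head = nn.Dense(4, 2, rng=np.random.default_rng(2))
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal((6, 4))
            assert classify(x, head).sum() == pytest.approx(1.0, abs=1e-6)

    def test_gap_of_constant_tokens(self):
        head = nn.Dense(3, 2, rng=np.random.default_rng(3))
        v = np.array([0.3, -1.2, 0.7])
        x = np.tile(v, (6, 1))
        expected = nn.softmax(v @ head.params["W"] + head.params["b"])
        np.testing.assert_allclose(classify(x, head), expected, atol=1e-6)


class TestMixerNet:
    def test_config_validation(self):
        with pytest.raises(ParameterError):
            ModelConfig(n_mixer_blocks=0)
        with pytest.raises(ParameterError):
            ModelConfig(tokens=16)  # inconsistent with 224x112 through 5 pools
        with pytest.raises(ParameterError):
            MixerNet(ModelConfig(pretrained=True))

    def test_forward_shapes_and_gradient_flow(self, small_net):
        """Every trainable tensor receives a nonzero gradient for a generic
        batch — no dead branches."""
        x = np.random.default_rng(0).random((2, 224, 112, 3)).astype(np.float32)
        logits = small_net.forward(x)
        assert logits.shape == (2, 2)
        assert small_net.feature_map.shape == (2, 7, 3, 32)
        loss, dl = nn.softmax_cross_entropy(logits, np.array([0, 1]))
        for l in small_net.trainable_layers:
            l.zero_grads()
        small_net.backward(dl)
        for i, l in enumerate(small_net.trainable_layers):
            for k, g in l.grads.items():
                assert np.abs(g).max() > 0, f"dead gradient: layer {i} param {k}"

    def test_save_load_round_trip(self, small_net, tmp_path):
        x = np.random.default_rng(1).random((2, 224, 112, 3)).astype(np.float32)
        p1 = small_net.predict_proba(x)
        small_net.save(tmp_path / "ckpt")
        net2 = MixerNet.load(tmp_path / "ckpt")
        np.testing.assert_allclose(net2.predict_proba(x), p1, atol=1e-7)
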