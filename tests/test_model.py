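"""Architecture contracts: patch algebra, layer shapes, parameter counts,
loss, and short-horizon training behaviour on tiny configurations."""

import numpy as np
import pytest

from abisa.model import (
    ModelConfig,
    TrainConfig,
    build_abisa,
    build_standard_vit,
    count_trainable_parameters,
    extract_patches,
    assemble_patches,
    load_model,
    predict_tiles,
    save_model,
    sparse_categorical_cross_entropy,
    train,
)
from abisa.nn.autograd import Tensor
from abisa.nn.layers import LSTM


TINY = ModelConfig(image_size=16, patch_size=4, projection_dim=12, num_heads=2,
                   key_dim=6, transformer_layers=2, lstm_units=5,
                   mlp_head_units=(16, 8), attention_dropout=0.0, head_dropout=0.0)


def tiny_images(n, rng_seed=0, size=16):
    return np.random.default_rng(rng_seed).random((n, size, size, 3)).astype(np.float32)


class TestPatchAlgebra:
    def test_64px_image_yields_100_patches_of_108(self):
        img = np.arange(64 * 64 * 3).reshape(64, 64, 3) % 256
        patches = extract_patches(img, 6)
        assert patches.shape == (100, 108)

    def test_single_patch_identity(self):
        img = np.random.default_rng(0).random((6, 6, 3))
        patches = extract_patches(img, 6)
        assert patches.shape == (1, 108)
        assert np.array_equal(patches[0], img.ravel())

    def test_partition_reassembles_original(self):
        img = np.random.default_rng(1).random((12, 12, 3))
        patches = extract_patches(img, 6)
        assert patches.shape == (4, 108)
        assert np.array_equal(assemble_patches(patches, 12, 6), img)

    def test_patch_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            extract_patches(np.zeros((4, 4, 3)), 6)

    def test_config_recomputes_patch_count(self):
        cfg = ModelConfig()
        assert cfg.num_patches == 100
        assert ModelConfig(image_size=60, patch_size=6).num_patches == 100
        assert ModelConfig(image_size=66, patch_size=6).num_patches == 121


class TestPatchEncoder:
    def test_zero_projection_returns_position_table(self):
        model = build_abisa(TINY, seed=0)
        enc = model.encoder
        enc.projection.kernel.data[:] = 0
        enc.projection.bias.data[:] = 0
        out = enc(Tensor(np.random.default_rng(0).random((2, TINY.num_patches,
                                                          TINY.patch_dim)).astype(np.float32)))
        assert np.allclose(out.data, enc.position_embedding.data[None], atol=1e-6)

    def test_output_width_matches_projection_dim(self):
        model = build_abisa(ModelConfig(), seed=0)
        x = Tensor(np.zeros((1, 100, 108), dtype=np.float32))
        assert model.encoder(x).shape == (1, 100, 64)

    def test_identical_patches_at_different_positions_encode_differently(self):
        model = build_abisa(TINY, seed=0)
        same = np.tile(np.random.default_rng(2).random(TINY.patch_dim)
                       .astype(np.float32), (1, TINY.num_patches, 1))
        out = model.encoder(Tensor(same)).data[0]
        assert not np.allclose(out[0], out[1])


class TestTransformerBlock:
    def test_shape_preserved(self):
        model = build_abisa(TINY, seed=0)
        x = Tensor(np.random.default_rng(3).random(
            (2, TINY.num_patches, TINY.projection_dim)).astype(np.float32))
        out = model.blocks[0](x)
        assert out.shape == x.shape

    def test_attention_rows_are_distributions(self):
        model = build_abisa(TINY, seed=0)
        x = Tensor(np.random.default_rng(4).random(
            (2, TINY.num_patches, TINY.projection_dim)).astype(np.float32))
        model.blocks[0](x)
        probs = model.blocks[0].attention._last_attention
        assert probs.shape[-1] == TINY.num_patches
        assert np.allclose(probs.sum(axis=-1), 1.0, atol=1e-5)
        assert (probs >= 0).all()

    def test_zero_output_projection_degenerates_to_layernorm(self):
        model = build_abisa(TINY, seed=0)
        block = model.blocks[0]
        block.attention.wo.kernel.data[:] = 0
        block.attention.wo.bias.data[:] = 0
        x = Tensor(np.random.default_rng(5).random(
            (1, TINY.num_patches, TINY.projection_dim)).astype(np.float32))
        expected = block.norm(x)
        assert np.allclose(block(x).data, expected.data, atol=1e-6)


class TestLSTM:
    def test_output_sequence_shape(self):
        rng = np.random.default_rng(0)
        lstm = LSTM(rng, 64, 32)
        x = Tensor(rng.random((2, 100, 64)).astype(np.float32))
        assert lstm(x).shape == (2, 100, 32)

    def test_parameter_count_formula(self):
        lstm = LSTM(np.random.default_rng(0), 64, 32)
        count = sum(p.size for p in lstm.parameters())
        assert count == 4 * ((64 + 32) * 32 + 32) == 12_416

    def test_zero_input_zero_bias_fixed_point(self):
        lstm = LSTM(np.random.default_rng(0), 8, 4)
        lstm.bias.data[:] = 0
        out = lstm(Tensor(np.zeros((1, 5, 8), dtype=np.float32)))
        assert np.allclose(out.data, 0.0)


class TestParameterCounts:
    @staticmethod
    def closed_form(cfg: ModelConfig, with_lstm: bool) -> int:
        """Layer-by-layer sum, independent of the network classes."""
        p, d = cfg.num_patches, cfg.projection_dim
        total = cfg.patch_dim * d + d + p * d  # projection + positions
        hk = cfg.num_heads * cfg.key_dim
        mha = 3 * (d * hk + hk) + hk * d + d
        block = mha + 2 * d  # attention + layer norm
        if cfg.use_block_ffn:
            dims = [d, *cfg.ffn_units()]
            block += sum(dims[i] * dims[i + 1] + dims[i + 1]
                         for i in range(len(dims) - 1))
            block += 2 * dims[-1]
        total += cfg.transformer_layers * block
        width = d
        if with_lstm:
            total += 4 * ((d + cfg.lstm_units) * cfg.lstm_units + cfg.lstm_units)
            width = cfg.lstm_units
        total += 2 * width  # final layer norm
        dims = [p * width, *cfg.mlp_head_units, cfg.num_classes]
        total += sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))
        return total

    @pytest.mark.parametrize("use_ffn", [False, True])
    def test_counts_match_closed_form(self, use_ffn):
        cfg = ModelConfig(use_block_ffn=use_ffn)
        assert count_trainable_parameters(build_abisa(cfg)) == self.closed_form(cfg, True)
        assert count_trainable_parameters(build_standard_vit(cfg)) == self.closed_form(cfg, False)

    def test_reference_totals(self):
        assert count_trainable_parameters(build_abisa(ModelConfig())) == 8_947_714
        assert count_trainable_parameters(build_standard_vit(ModelConfig())) == 15_488_962

    @pytest.mark.parametrize("cfg", [ModelConfig(), ModelConfig(use_block_ffn=True), TINY])
    def test_lstm_variant_is_smaller(self, cfg):
        # flattened pre-head width num_patches*lstm_units < num_patches*projection_dim
        assert (count_trainable_parameters(build_abisa(cfg))
                < count_trainable_parameters(build_standard_vit(cfg)))

    def test_counts_are_functions_of_config_only(self):
        a = count_trainable_parameters(build_abisa(TINY, seed=1))
        b = count_trainable_parameters(build_abisa(TINY, seed=99))
        assert a == b


class TestForwardAndLoss:
    def test_softmax_probabilities(self):
        model = build_abisa(TINY, seed=0)
        probs, labels = predict_tiles(model, tiny_images(3))
        assert probs.shape == (3, 2)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-5)
        assert set(labels) <= {0, 1}

    def test_inference_is_deterministic(self):
        model = build_abisa(ModelConfig(), seed=0)
        x = np.random.default_rng(0).random((2, 64, 64, 3)).astype(np.float32)
        a, _ = predict_tiles(model, x)
        b, _ = predict_tiles(model, x)
        assert np.array_equal(a, b)

    def test_white_noise_input_is_numerically_stable(self):
        model = build_abisa(TINY, seed=0)
        probs, _ = predict_tiles(model, tiny_images(8, rng_seed=9))
        assert np.isfinite(probs).all()

    def test_loss_matches_hand_computed_two_example_batch(self):
        logits = Tensor(np.array([[2.0, 0.0], [0.5, 1.5]], dtype=np.float32))
        loss = sparse_categorical_cross_entropy(logits, np.array([0, 1]))
        expected = -(np.log(np.exp(2) / (np.exp(2) + 1))
                     + np.log(np.exp(1.5) / (np.exp(0.5) + np.exp(1.5)))) / 2
        assert float(loss.data) == pytest.approx(expected, rel=1e-5)

    def test_initial_loss_near_ln2_on_balanced_data(self):
        model = build_abisa(TINY, seed=3)
        logits = model.forward(tiny_images(20))
        loss = sparse_categorical_cross_entropy(logits, np.array([0, 1] * 10))
        assert float(loss.data) == pytest.approx(np.log(2), abs=0.2)

    def test_label_out_of_range_rejected(self):
        model = build_abisa(TINY, seed=0)
        logits = model.forward(tiny_images(2))
        with pytest.raises(ValueError):
            sparse_categorical_cross_entropy(logits, np.array([0, 2]))


class TestTraining:
    def test_single_batch_loss_decreases(self):
        model = build_abisa(TINY, seed=0)
        x = tiny_images(8, rng_seed=1)
        y = np.array([0, 1] * 4)
        cfg = TrainConfig(epochs=5, batch_size=8, learning_rate=3e-4, seed=0,
                          early_stop_on_val=False)
        history = train(model, x, y, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_training_is_bit_reproducible(self):
        runs = []
        for _ in range(2):
            model = build_abisa(TINY, seed=7)
            train(model, tiny_images(8, rng_seed=2), np.array([0, 1] * 4),
                  TrainConfig(epochs=2, batch_size=4, seed=7, early_stop_on_val=False))
            runs.append(model.get_weights())
        for a, b in zip(*runs):
            assert np.array_equal(a, b)

    def test_early_stopping_restores_best_validation_weights(self):
        model = build_abisa(TINY, seed=1)
        x, y = tiny_images(12, rng_seed=3), np.array([0, 1] * 6)
        vx, vy = tiny_images(6, rng_seed=4), np.array([0, 1] * 3)
        history = train(model, x, y,
                        TrainConfig(epochs=4, batch_size=6, seed=1),
                        val_images=vx, val_labels=vy)
        best = int(np.argmin(history["val_loss"]))
        probs, _ = predict_tiles(model, vx)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(len(vy)), vy] + eps))
        assert loss == pytest.approx(history["val_loss"][best], abs=1e-5)

    def test_save_load_roundtrip(self, tmp_path):
        model = build_abisa(TINY, seed=2)
        x = tiny_images(3, rng_seed=5)
        save_model(model, tmp_path / "ckpt")
        clone = load_model(tmp_path / "ckpt")
        assert np.array_equal(model.predict_proba(x), clone.predict_proba(x))
        assert clone.with_lstm
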