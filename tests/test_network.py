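"""Architecture contracts: shapes, channel widths, GRU semantics, sequence
flexibility, parameter-count invariance, checkpoints."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from refocus.network import (DiscriminatorConfig, Discriminator,
                             GeneratorConfig, RecurrentGenerator,
                             count_parameters, load_checkpoint,
                             save_checkpoint)
from refocus.nn import ConvGRUCell
from refocus.nn.autodiff import Tensor


def literal_gru_step(x, h, cell):
    """Independent loop-based evaluation of the gated update:
    f = sigmoid(Wf*x + Uf*h + bf); hhat = tanh(Wh*x + Uh*(f.h) + bh);
    h' = (1-f).h + f.hhat   -- using scipy correlate2d per channel pair."""
    def conv(inp, w):
        n, cin, H, W = inp.shape
        cout = w.shape[0]
        out = np.zeros((n, cout, H, W))
        for b in range(n):
            for o in range(cout):
                acc = np.zeros((H, W))
                for c in range(cin):
                    acc += correlate2d(inp[b, c], w[o, c], mode="same",
                                       boundary="fill")
                out[b, o] = acc
        return out
    wf, uf, bf = cell.w_f.data, cell.u_f.data, cell.b_f.data
    wh, uh, bh = cell.w_h.data, cell.u_h.data, cell.b_h.data
    f = 1.0 / (1.0 + np.exp(-(conv(x, wf) + conv(h, uf)
                              + bf[None, :, None, None])))
    hhat = np.tanh(conv(x, wh) + conv(f * h, uh) + bh[None, :, None, None])
    return (1.0 - f) * h + f * hhat


class TestConvGRU:
    def test_zero_weights_zero_state(self):
        # all weights/biases zero, h0 = 0: f = 0.5, hhat = 0, h1 = 0
        cell = ConvGRUCell(2, np.random.default_rng(0))
        for p in cell.parameters():
            p.data[:] = 0
        x = Tensor(np.random.default_rng(1).normal(size=(1, 2, 8, 8))
                   .astype(np.float32))
        h = cell.init_state(1, 8, 8)
        h1 = cell.step(x, h)
        np.testing.assert_array_equal(h1.data, 0.0)

    def test_zero_weights_halving_recursion(self):
        # with zero weights, h_t = 0.5 * h_{t-1} exactly
        cell = ConvGRUCell(1, np.random.default_rng(0))
        for p in cell.parameters():
            p.data[:] = 0
        H = np.random.default_rng(2).normal(size=(1, 1, 8, 8)).astype(np.float32)
        h = Tensor(H.copy())
        x = Tensor(np.zeros_like(H))
        for t in range(1, 4):
            h = cell.step(x, h)
            np.testing.assert_allclose(h.data, H * 0.5 ** t, rtol=1e-6)

    def test_matches_literal_equation_evaluation(self):
        cell = ConvGRUCell(3, np.random.default_rng(5))
        rng = np.random.default_rng(6)
        x = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        h = rng.normal(size=(2, 3, 6, 6)).astype(np.float32)
        ours = cell.step(Tensor(x), Tensor(h)).data
        oracle = literal_gru_step(x.astype(np.float64), h.astype(np.float64),
                                  cell)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_state_bounded_by_convex_combination(self):
        cell = ConvGRUCell(2, np.random.default_rng(7))
        rng = np.random.default_rng(8)
        x = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        h = Tensor(rng.normal(size=(1, 2, 8, 8)).astype(np.float32))
        h1 = cell.step(x, h)
        bound = np.maximum(np.abs(h.data), 1.0)
        assert np.all(np.abs(h1.data) <= bound + 1e-6)


class TestGeneratorArchitecture:
    def test_channel_width_formula(self):
        cfg = GeneratorConfig(n_scales=5, base_channels=20)
        gen = RecurrentGenerator(cfg, seed=0)
        # stem: base channels at both convs (k=1 has no pooling)
        assert gen.encoder[0].conv1.weight.shape[0] == 20
        assert gen.encoder[0].conv2.weight.shape[0] == 20
        for k in range(2, 6):
            blk = gen.encoder[k - 1]
            assert blk.conv1.weight.shape[0] == 20 * 2 ** (k - 2)
            assert blk.conv2.weight.shape[0] == 20 * 2 ** (k - 1)
            assert blk.pool

    def test_encoder_decoder_shape_arithmetic(self):
        # hand oracle: K-1 poolings down, K-1 up-samplings back
        for K, size in [(3, 64), (4, 128), (5, 256)]:
            cfg = GeneratorConfig(n_scales=K, base_channels=2)
            gen = RecurrentGenerator(cfg, seed=0).eval()
            x = np.zeros((1, 1, 2, size, size), dtype=np.float32)
            feats = gen.encode(Tensor(x[0]))
            assert feats[-1].shape[2] == size // 2 ** (K - 1)
            out = gen.forward(x)
            assert out.shape == (1, 1, size, size)

    def test_indivisible_dims_rejected(self):
        gen = RecurrentGenerator(GeneratorConfig(n_scales=4, base_channels=2),
                                 seed=0)
        x = np.zeros((1, 1, 2, 36, 36), dtype=np.float32)
        with pytest.raises(ValueError):
            gen.forward(x)

    def test_doubling_base_doubles_widths(self):
        a = GeneratorConfig(n_scales=4, base_channels=8)
        b = GeneratorConfig(n_scales=4, base_channels=16)
        for k in range(1, 5):
            assert b.scale_channels(k) == 2 * a.scale_channels(k)

    def test_recurrent_block_residual_identity(self):
        gen = RecurrentGenerator(GeneratorConfig(n_scales=3, base_channels=4),
                                 seed=1)
        for blk in gen.recurrent:
            blk.proj.weight.data[:] = 0
            blk.proj.bias.data[:] = 0
        rng = np.random.default_rng(2)
        x = Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        state = gen.init_state(1, 16, 16)
        s, _ = gen.recurrent[0].step(x, state.hidden[0])
        np.testing.assert_array_equal(s.data, x.data)

    def test_state_evolves_across_steps(self):
        gen = RecurrentGenerator(GeneratorConfig(n_scales=3, base_channels=4),
                                 seed=3).eval()
        rng = np.random.default_rng(4)
        x = Tensor(rng.normal(size=(1, 4, 16, 16)).astype(np.float32))
        state = gen.init_state(1, 16, 16)
        s1, h1 = gen.recurrent[0].step(x, state.hidden[0])
        s2, h2 = gen.recurrent[0].step(x, h1)
        assert not np.allclose(h1.data, h2.data)
        assert not np.allclose(s1.data, s2.data)

    def test_stale_state_rejected(self):
        gen = RecurrentGenerator(GeneratorConfig(n_scales=3, base_channels=2),
                                 seed=0)
        state = gen.init_state(1, 16, 16)
        gen.init_state(1, 16, 16)  # new sequence supersedes the old state
        x = Tensor(np.zeros((1, 2, 16, 16), dtype=np.float32))
        with pytest.raises(RuntimeError):
            gen.step(x, state)


class TestGeneratorForward:
    @pytest.mark.parametrize("M", [1, 2, 3, 6])
    def test_sequence_length_flexibility(self, tiny_model, M):
        x = np.random.default_rng(M).normal(size=(1, M, 2, 32, 32)) \
            .astype(np.float32)
        out = tiny_model.eval().forward(x)
        assert out.shape == (1, 1, 32, 32)

    def test_parameter_count_independent_of_m(self, tiny_model):
        n0 = count_parameters(tiny_model)
        for M in (1, 2, 3, 6):
            x = np.zeros((1, M, 2, 32, 32), dtype=np.float32)
            tiny_model.eval().forward(x)
            assert count_parameters(tiny_model) == n0

    def test_inference_determinism(self, tiny_model):
        x = np.random.default_rng(9).normal(size=(1, 3, 2, 32, 32)) \
            .astype(np.float32)
        a = tiny_model.eval().forward(x).data
        b = tiny_model.eval().forward(x).data
        np.testing.assert_array_equal(a, b)

    def test_empty_sequence_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            tiny_model.forward(np.zeros((1, 0, 2, 32, 32), dtype=np.float32))


class TestParameterCount:
    def test_positive_and_conv_scaling(self):
        small = RecurrentGenerator(GeneratorConfig(n_scales=3,
                                                   base_channels=8), seed=0)
        big = RecurrentGenerator(GeneratorConfig(n_scales=3,
                                                 base_channels=16), seed=0)
        n_small, n_big = count_parameters(small), count_parameters(big)
        assert n_small > 0
        # conv-dominated: weights scale ~4x when widths double
        assert 3.3 < n_big / n_small < 4.2


class TestDiscriminator:
    def test_output_in_unit_interval(self):
        d = Discriminator(DiscriminatorConfig(n_blocks=3, base_channels=2),
                          seed=0)
        x = np.random.default_rng(1).normal(size=(2, 32, 32)).astype(np.float32)
        out = d.eval().forward(x)
        assert out.data.shape == (2, 1)
        assert np.all((out.data > 0) & (out.data < 1))

    def test_block_width_formula(self):
        cfg = DiscriminatorConfig()
        d = Discriminator(cfg, seed=0)
        for k in range(1, 6):
            assert cfg.block_channels(k) == 20 * 2 ** k
            assert d.blocks[k - 1].conv1.weight.shape[0] == 20 * 2 ** k
            assert d.blocks[k - 1].conv2.weight.shape[0] == 20 * 2 ** k

    def test_pooled_vector_matches_last_width(self):
        cfg = DiscriminatorConfig(n_blocks=3, base_channels=2)
        d = Discriminator(cfg, seed=0)
        assert d.fc1.weight.shape[0] == cfg.block_channels(3)

    def test_too_small_input_rejected(self):
        d = Discriminator(DiscriminatorConfig(n_blocks=3, base_channels=2),
                          seed=0)
        with pytest.raises(ValueError):
            d.forward(np.zeros((4, 4), dtype=np.float32))


def test_checkpoint_roundtrip_bit_exact(tmp_path, tiny_model):
    x = np.random.default_rng(13).normal(size=(1, 2, 2, 32, 32)) \
        .astype(np.float32)
    before = tiny_model.eval().forward(x).data
    path = tmp_path / "ckpt.npz"
    save_checkpoint(path, tiny_model, metadata={"note": "test"})
    restored, meta = load_checkpoint(path)
    assert meta["note"] == "test"
    after = restored.eval().forward(x).data
    np.testing.assert_array_equal(before, after)
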