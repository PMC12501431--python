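"""Transformer decoder: layer semantics, attention algebra, gradients."""

import math
import warnings

import numpy as np
import pytest

from ssvepkit import (
    AETFConfig, AETFModel, make_student, multihead_attention,
    positional_encoding, scaled_dot_attention, save_checkpoint, load_checkpoint,
)
from ssvepkit import nn
from ssvepkit.train_eval import batch_loss


def tiny_cfg(**kw):
    base = dict(n_channels=4, n_samples=32, n_classes=4, fs=64.0,
                n_spatial=8, n_freq_filters=4, n_layers=1, dropout=0.0)
    base.update(kw)
    return AETFConfig(**base)


class TestConfig:
    def test_defaults_follow_published_settings(self):
        cfg = AETFConfig(n_channels=8, n_samples=125, n_classes=12, fs=250.0)
        assert cfg.n_spatial == 16          # twice the electrode count
        assert cfg.n_freq_filters == 8
        assert cfg.n_layers == 2
        assert cfg.d_model == 16 * 8        # N_sp * N_fr
        assert cfg.n_heads == 8             # one head per frequency filter
        assert cfg.kernel_len == 125        # floor(fs / 2)

    def test_head_divisibility_enforced(self):
        with pytest.raises(ValueError):
            AETFConfig(n_channels=3, n_samples=16, n_classes=2, fs=32.0,
                       n_spatial=3, n_freq_filters=3, n_heads=4)

    def test_short_window_clips_kernel_with_warning(self):
        cfg = tiny_cfg(n_samples=16, fs=250.0)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            assert cfg.kernel_len == 16
        assert any("clipping" in str(w.message) for w in rec)


class TestSpatialFC:
    def test_zero_weights_give_zero_output(self):
        m = AETFModel(tiny_cfg(), seed=0)
        m.params["fc_w"].data[:] = 0.0
        m.params["fc_b"].data[:] = 0.0
        x = nn.Tensor(np.random.default_rng(0).standard_normal((1, 4, 32)))
        h = (x.transpose(0, 2, 1) @ m.params["fc_w"] + m.params["fc_b"]).tanh()
        assert np.allclose(h.data, 0.0)

    def test_identity_weights_linear_regime(self):
        # tanh(x) ~ x for |x| < 0.05: |tanh(x) - x| <= |x|^3/3 < 4.2e-5
        W = np.zeros((4, 8))
        W[np.arange(4), np.arange(4)] = 1.0
        x = np.random.default_rng(1).uniform(-0.05, 0.05, (4, 32))
        out = np.tanh(x.T @ W).T
        assert np.max(np.abs(out[:4] - x)) < 1e-3

    def test_output_inside_unit_interval(self):
        m = AETFModel(tiny_cfg(), seed=0).eval()
        x = 100 * np.random.default_rng(2).standard_normal((2, 4, 32))
        h = (nn.Tensor(x).transpose(0, 2, 1) @ m.params["fc_w"]
             + m.params["fc_b"]).tanh()
        assert np.all(np.abs(h.data) <= 1.0)  # tanh saturates in float at +/-1


class TestFreqConv:
    def test_delta_kernel_is_identity_on_nonnegative_input(self):
        x = np.abs(np.random.default_rng(0).standard_normal((1, 3, 16)))
        L = 5
        k = np.zeros((1, L))
        k[0, (L - 1) // 2] = 1.0   # centred delta
        out = nn.conv1d_same(nn.Tensor(x), nn.Tensor(k), nn.Tensor(np.zeros(1)))
        np.testing.assert_allclose(out.data[0, 0], x[0], atol=1e-14)

    def test_output_shape_contract(self):
        # 8 frequency filters on a (16 x 125) map -> (8, 16, 125)
        x = np.random.default_rng(1).standard_normal((1, 16, 125))
        k = np.random.default_rng(2).standard_normal((8, 25))
        out = nn.conv1d_same(nn.Tensor(x), nn.Tensor(k), nn.Tensor(np.zeros(8)))
        assert out.data.shape == (1, 8, 16, 125)

    def test_moving_average_matches_fft_oracle(self):
        # steady-state gain of a length-L moving average on a pure sinusoid
        fs, f0, L, n = 128.0, 8.0, 9, 1024
        t = np.arange(n) / fs
        sig = np.cos(2 * np.pi * f0 * t)[None, None, :]
        k = np.full((1, L), 1.0 / L)
        out = nn.conv1d_same(nn.Tensor(sig), nn.Tensor(k), nn.Tensor(np.zeros(1)))
        gain_meas = np.std(out.data[0, 0, 0, L:-L]) / np.std(sig[0, 0, L:-L])
        # oracle: magnitude of the kernel's DTFT at f0
        om = 2 * np.pi * f0 / fs
        gain_fft = abs(np.sum(k[0] * np.exp(-1j * om * np.arange(L))))
        assert abs(gain_meas - gain_fft) < 1e-6


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 6)
        np.testing.assert_allclose(pe[0, 0::2], 0.0)
        np.testing.assert_allclose(pe[0, 1::2], 1.0)

    def test_first_position_first_dim_is_sin_one(self):
        for d in (4, 16, 64):
            assert positional_encoding(2, d)[1, 0] == pytest.approx(math.sin(1.0))

    def test_rows_pairwise_distinct(self):
        pe = positional_encoding(2000, 16)
        # lexicographic uniqueness of rows
        assert len(np.unique(pe.round(12), axis=0)) == 2000

    def test_odd_dim_rejected(self):
        with pytest.raises(ValueError):
            positional_encoding(4, 5)


class TestScaledDotAttention:
    def test_single_key_returns_value(self):
        out = scaled_dot_attention(np.random.standard_normal((3, 2)),
                                   np.ones((1, 2)), np.array([[5.0, 7.0]]))
        np.testing.assert_allclose(out.data, np.tile([5.0, 7.0], (3, 1)))

    def test_identical_values_collapse(self):
        rng = np.random.default_rng(0)
        V = np.tile([[1.0, 2.0]], (4, 1))
        out = scaled_dot_attention(rng.standard_normal((3, 5)),
                                   rng.standard_normal((4, 5)), V)
        np.testing.assert_allclose(out.data, np.tile([1.0, 2.0], (3, 1)))

    def test_hand_computed_two_key_example(self):
        # scores (1/sqrt(2), 0); softmax -> p = 1/(1+exp(-1/sqrt(2)))
        out = scaled_dot_attention(np.array([[1.0, 0.0]]),
                                   np.array([[1.0, 0.0], [0.0, 1.0]]),
                                   np.array([[1.0], [0.0]]))
        p = 1.0 / (1.0 + math.exp(-1.0 / math.sqrt(2.0)))
        assert abs(out.data[0, 0] - p) < 1e-12
        assert out.data[0, 0] == pytest.approx(0.6698, abs=1e-4)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            scaled_dot_attention(np.zeros((2, 3)), np.zeros((2, 4)), np.zeros((2, 1)))


class TestMultiheadAttention:
    def test_single_head_identity_projections_reduce_to_plain_attention(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 4))
        I = np.eye(4)
        out = multihead_attention(X, 1, I, I, I, I)
        ref = scaled_dot_attention(X, X, X)
        np.testing.assert_allclose(out.data, ref.data, atol=1e-12)

    def test_output_shape_for_valid_head_counts(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 8))
        for h in (1, 2, 4, 8):
            W = rng.standard_normal((4, 8, 8))
            out = multihead_attention(X, h, W[0], W[1], W[2], W[3])
            assert out.data.shape == (6, 8)

    def test_permutation_equivariance_without_positions(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((7, 8))
        W = rng.standard_normal((4, 8, 8))
        perm = rng.permutation(7)
        out = multihead_attention(X, 2, W[0], W[1], W[2], W[3]).data
        out_p = multihead_attention(X[perm], 2, W[0], W[1], W[2], W[3]).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


class TestModelForward:
    def test_published_config_logit_length(self):
        cfg = AETFConfig(n_channels=8, n_samples=125, n_classes=12, fs=250.0)
        m = AETFModel(cfg, seed=0).eval()
        logits = m.forward(np.random.default_rng(0).standard_normal((8, 125)))
        assert logits.data.shape == (12,)

    def test_eval_forward_deterministic(self):
        m = AETFModel(tiny_cfg(dropout=0.3), seed=0).eval()
        x = np.random.default_rng(1).standard_normal((2, 4, 32))
        np.testing.assert_array_equal(m.forward(x).data, m.forward(x).data)

    def test_attention_rows_sum_to_one_every_layer_and_head(self):
        m = AETFModel(tiny_cfg(n_layers=2), seed=0).eval()
        m.collect_attention = True
        m.forward(np.random.default_rng(2).standard_normal((3, 4, 32)))
        assert len(m.attention_weights) == 2
        for w in m.attention_weights:
            assert np.all(w >= 0)
            np.testing.assert_allclose(w.sum(axis=-1), 1.0, atol=1e-6)

    def test_encoder_ablation_still_classifies(self):
        m = AETFModel(tiny_cfg(use_encoder=False), seed=0).eval()
        logits = m.forward(np.random.default_rng(3).standard_normal((2, 4, 32)))
        assert logits.data.shape == (2, 4)

    def test_gradient_matches_finite_differences(self):
        m = AETFModel(tiny_cfg(), seed=0)
        rng = np.random.default_rng(4)
        X = rng.standard_normal((4, 4, 32))
        y = rng.integers(0, 4, 4)
        m.train()
        loss = batch_loss(m, X, y)
        loss.backward()
        bn_state = (m.bn_mean.copy(), m.bn_var.copy())
        for name in ("fc_w", "conv_k", "enc0_wq", "enc0_ff1_w", "head_w"):
            p = m.params[name]
            idx = tuple(s // 2 for s in p.data.shape)
            g = p.grad[idx]
            eps, old = 1e-6, p.data[idx]
            p.data[idx] = old + eps
            m.bn_mean, m.bn_var = bn_state[0].copy(), bn_state[1].copy()
            lp = batch_loss(m, X, y).item()
            p.data[idx] = old - eps
            m.bn_mean, m.bn_var = bn_state[0].copy(), bn_state[1].copy()
            lm = batch_loss(m, X, y).item()
            p.data[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(g - fd) / max(abs(fd), 1e-8) < 1e-4, name


class TestStudent:
    def test_student_halves_width_and_depth(self):
        teacher = AETFConfig(n_channels=8, n_samples=32, n_classes=12, fs=64.0)
        student = make_student(teacher)
        assert student.n_layers == 1
        assert student.d_model == teacher.d_model // 2

    def test_student_has_fewer_parameters_and_valid_logits(self):
        tcfg = tiny_cfg(n_layers=2)
        t = AETFModel(tcfg, seed=0)
        s = AETFModel(make_student(tcfg), seed=0)
        assert s.n_parameters() < t.n_parameters()
        out = s.eval().forward(np.zeros((4, 32)))
        assert out.data.shape == (4,)

    def test_head_count_reduced_when_needed(self):
        cfg = AETFConfig(n_channels=3, n_samples=16, n_classes=2, fs=32.0,
                         n_spatial=6, n_freq_filters=2, n_heads=4)
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            student = make_student(cfg)
        assert student.d_model % student.n_heads == 0
        assert any("head count" in str(w.message) for w in rec)


def test_checkpoint_roundtrip(tmp_path):
    m = AETFModel(tiny_cfg(), seed=1).eval()
    x = np.random.default_rng(5).standard_normal((2, 4, 32))
    ref = m.forward(x).data
    save_checkpoint(m, tmp_path / "m.h5")
    m2 = load_checkpoint(tmp_path / "m.h5")
    np.testing.assert_array_equal(m2.eval().forward(x).data, ref)
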