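"""Fusion cell and interaction layer against independent scalar/loop oracles."""

import numpy as np
import pytest

from idrfuse._autodiff import Tensor
from idrfuse.network import (
    FusionCellParams,
    FusionState,
    LSTMParams,
    ModelConfig,
    FusionNetwork,
    _run_recurrent_t,
    fused_memory,
    fusion_cell_step,
    run_interaction_layer,
)


def _zero_params(d_h, d_b, d_p):
    p = FusionCellParams.init(d_h, d_b, d_p, np.random.default_rng(0))
    for t in p.tensors():
        t.data[:] = 0.0
    return p


def _random_params(d_h, d_b, d_p, seed):
    return FusionCellParams.init(d_h, d_b, d_p, np.random.default_rng(seed))


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _reference_step(C, h, rb, rp, p):
    """Independent plain-numpy evaluation of the fusion-cell equations."""
    Cb = _sigmoid(p.W_c.data @ C + p.b_c.data) * _sigmoid(p.W_r.data @ rb + p.b_r.data)
    x = np.concatenate([rp, h])
    gates = _sigmoid(p.W_g.data @ x + p.b_g.data)
    d = p.d_h
    f, i, o = gates[:d], gates[d:2 * d], gates[2 * d:]
    chat = np.tanh(p.W_chat.data @ x + p.b_chat.data)
    C_new = f * Cb + i * chat
    return C_new, o * np.tanh(C_new)


class TestFusedMemory:
    def test_all_zero_parameters_give_quarter(self):
        p = _zero_params(4, 6, 8)
        out = fused_memory(np.random.default_rng(1).normal(size=4),
                           np.random.default_rng(2).normal(size=6), p)
        np.testing.assert_allclose(out, 0.25, atol=1e-12)

    def test_saturated_gates_approach_one(self):
        p = _zero_params(3, 5, 7)
        p.b_c.data[:] = 20.0
        p.b_r.data[:] = 20.0
        out = fused_memory(np.zeros(3), np.zeros(5), p)
        np.testing.assert_allclose(out, 1.0, atol=1e-8)

    def test_scalar_oracle(self):
        p = _zero_params(1, 3, 2)
        p.W_c.data[:] = 1.0
        w_r = np.array([0.2, 0.3, 0.2])
        p.W_r.data[0] = w_r
        r_b = np.array([1.0, 1.0, 1.0])  # w_r . r_b = 0.7
        out = fused_memory(np.array([0.3]), r_b, p)
        expected = _sigmoid(0.3) * _sigmoid(0.7)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_output_strictly_in_unit_interval(self):
        p = _random_params(8, 10, 12, seed=3)
        rng = np.random.default_rng(4)
        for _ in range(20):
            out = fused_memory(rng.normal(size=8) * 5, rng.normal(size=10) * 5, p)
            assert ((out > 0) & (out < 1)).all()

    def test_shape_mismatch_is_an_error(self):
        p = _random_params(4, 6, 8, seed=0)
        with pytest.raises(ValueError):
            fused_memory(np.zeros(5), np.zeros(6), p)


class TestFusionCellStep:
    def test_all_zero_closed_form(self):
        d_h = 5
        p = _zero_params(d_h, 7, 9)
        state = FusionState(C=np.random.default_rng(0).normal(size=d_h),
                            h=np.zeros(d_h))
        # with all parameters zero: gates 0.5, Chat 0, C^b 0.25,
        # C_new 0.125, h_new 0.5 * tanh(0.125)
        new = fusion_cell_step(state, np.ones(7), np.ones(9), p)
        np.testing.assert_allclose(new.C, 0.125, atol=1e-10)
        np.testing.assert_allclose(new.h, 0.5 * np.tanh(0.125), atol=1e-10)

    def test_scalar_hand_oracle(self):
        p = _zero_params(1, 1, 1)
        p.W_c.data[:] = 0.8
        p.b_c.data[:] = -0.1
        p.W_r.data[:] = 1.5
        p.b_r.data[:] = 0.2
        p.W_g.data[:] = np.array([[0.4, -0.3], [0.1, 0.6], [-0.2, 0.5]])
        p.b_g.data[:] = np.array([0.05, -0.05, 0.15])
        p.W_chat.data[:] = np.array([[0.7, -0.4]])
        p.b_chat.data[:] = 0.3
        C0, h0, rb, rp = 0.37, -0.21, 0.55, -0.8
        # independent step-by-step scalar computation
        Cb = _sigmoid(0.8 * C0 - 0.1) * _sigmoid(1.5 * rb + 0.2)
        f = _sigmoid(0.4 * rp - 0.3 * h0 + 0.05)
        i = _sigmoid(0.1 * rp + 0.6 * h0 - 0.05)
        o = _sigmoid(-0.2 * rp + 0.5 * h0 + 0.15)
        chat = np.tanh(0.7 * rp - 0.4 * h0 + 0.3)
        C_expected = f * Cb + i * chat
        h_expected = o * np.tanh(C_expected)
        new = fusion_cell_step(FusionState(np.array([C0]), np.array([h0])),
                               np.array([rb]), np.array([rp]), p)
        assert new.C[0] == pytest.approx(C_expected, abs=1e-10)
        assert new.h[0] == pytest.approx(h_expected, abs=1e-10)

    def test_matches_reference_step_on_random_inputs(self):
        rng = np.random.default_rng(5)
        p = _random_params(6, 4, 10, seed=6)
        C, h = rng.normal(size=6), np.tanh(rng.normal(size=6))
        rb, rp = rng.normal(size=4), rng.normal(size=10)
        new = fusion_cell_step(FusionState(C, h), rb, rp, p)
        C_ref, h_ref = _reference_step(C, h, rb, rp, p)
        np.testing.assert_allclose(new.C, C_ref, atol=1e-10)
        np.testing.assert_allclose(new.h, h_ref, atol=1e-10)

    def test_hidden_state_bounded_by_one(self):
        rng = np.random.default_rng(7)
        p = _random_params(6, 4, 10, seed=8)
        state = FusionState(rng.normal(size=6) * 10, np.zeros(6))
        for _ in range(30):
            state = fusion_cell_step(state, rng.normal(size=4) * 5,
                                     rng.normal(size=10) * 5, p)
            assert (np.abs(state.h) < 1).all()

    def test_wrong_plm_width_is_an_error(self):
        p = _random_params(4, 6, 8, seed=0)
        with pytest.raises(ValueError):
            fusion_cell_step(FusionState(np.zeros(4), np.zeros(4)),
                             np.zeros(6), np.zeros(7), p)


class TestInteractionLayer:
    def test_single_residue_equals_one_step_from_zero_state(self):
        p = _random_params(5, 4, 6, seed=1)
        rng = np.random.default_rng(2)
        rb, rp = rng.normal(size=(1, 4)), rng.normal(size=(1, 6))
        out = run_interaction_layer(rb, rp, p)
        step = fusion_cell_step(FusionState(np.zeros(5), np.zeros(5)),
                                rb[0], rp[0], p)
        np.testing.assert_allclose(out[0], step.h, atol=1e-12)

    @pytest.mark.parametrize("case", range(10))
    def test_equals_unrolled_reference_loop(self, case):
        rng = np.random.default_rng(100 + case)
        d_h = int(rng.integers(1, 9))
        L = int(rng.integers(1, 21))
        p = _random_params(d_h, 4, 6, seed=200 + case)
        Rb, Rp = rng.normal(size=(L, 4)), rng.normal(size=(L, 6))
        out = run_interaction_layer(Rb, Rp, p)
        C, h = np.zeros(d_h), np.zeros(d_h)
        for t in range(L):
            C, h = _reference_step(C, h, Rb[t], Rp[t], p)
            np.testing.assert_allclose(out[t], h, atol=1e-6)

    def test_padding_leaves_valid_rows_unchanged(self):
        rng = np.random.default_rng(3)
        p = _random_params(4, 4, 6, seed=4)
        Rb, Rp = rng.normal(size=(7, 4)), rng.normal(size=(7, 6))
        base = run_interaction_layer(Rb, Rp, p)
        Rb_pad = np.vstack([Rb, rng.normal(size=(3, 4))])
        Rp_pad = np.vstack([Rp, rng.normal(size=(3, 6))])
        mask = np.array([True] * 7 + [False] * 3)
        padded = run_interaction_layer(Rb_pad, Rp_pad, p, mask=mask)
        np.testing.assert_array_equal(padded[:7], base)
        assert np.all(padded[7:] == 0)

    def test_non_prefix_mask_is_an_error(self):
        p = _random_params(3, 4, 6, seed=0)
        mask = np.array([True, False, True])
        with pytest.raises(ValueError, match="prefix"):
            run_interaction_layer(np.zeros((3, 4)), np.zeros((3, 6)), p, mask)

    def test_bidirectional_width_and_backward_reversal(self):
        rng = np.random.default_rng(9)
        pf = _random_params(3, 4, 6, seed=10)
        pb = _random_params(3, 4, 6, seed=11)
        Rb, Rp = rng.normal(size=(5, 4)), rng.normal(size=(5, 6))
        out = run_interaction_layer(Rb, Rp, (pf, pb))
        assert out.shape == (5, 6)
        fw = run_interaction_layer(Rb, Rp, pf)
        bw = run_interaction_layer(Rb[::-1], Rp[::-1], pb)
        np.testing.assert_allclose(out[:, :3], fw, atol=1e-12)
        np.testing.assert_allclose(out[:, 3:], bw[::-1], atol=1e-12)


class TestConcatLstmEquivalence:
    """The concat_lstm baseline must equal a textbook LSTM on [R_b | R_p]."""

    @staticmethod
    def _textbook_lstm(X, W, b, d_h):
        """Independent plain-numpy LSTM (gate order f, i, o, candidate)."""
        C, h = np.zeros(d_h), np.zeros(d_h)
        out = []
        for x in X:
            z = W @ np.concatenate([x, h]) + b
            f = _sigmoid(z[:d_h])
            i = _sigmoid(z[d_h:2 * d_h])
            o = _sigmoid(z[2 * d_h:3 * d_h])
            g = np.tanh(z[3 * d_h:])
            C = f * C + i * g
            h = o * np.tanh(C)
            out.append(h.copy())
        return np.array(out)

    def test_matches_reference_lstm(self):
        rng = np.random.default_rng(12)
        d_h, d_b, d_p, L = 6, 4, 9, 15
        params = LSTMParams.init(d_h, d_b + d_p, np.random.default_rng(13))
        Rb, Rp = rng.normal(size=(L, d_b)), rng.normal(size=(L, d_p))
        mask = np.ones((1, L), dtype=bool)
        H = _run_recurrent_t(Rb[None], Rp[None], mask, params,
                             "concat_lstm", False).data[0]
        ref = self._textbook_lstm(np.hstack([Rb, Rp]), params.W.data,
                                  params.b.data, d_h)
        np.testing.assert_allclose(H, ref, atol=1e-6)


class TestExportHiddenStates:
    def test_tap_shapes_and_determinism(self):
        cfg = ModelConfig(d_b=5, d_p=7, d_h=4, d_model=8, n_layers=1,
                          n_heads=2, dropout=0.3, seed=1)
        net = FusionNetwork(cfg)
        rng = np.random.default_rng(0)
        Rb, Rp = rng.normal(size=(9, 5)), rng.normal(size=(9, 7))
        taps1 = net.export_hidden_states(Rb, Rp)
        taps2 = net.export_hidden_states(Rb, Rp)
        assert taps1["fused_h"].shape == (9, 4)
        assert taps1["encoder_out"].shape == (9, 8)
        assert taps1["traditional_in"].shape == (9, 5)
        assert taps1["plm_in"].shape == (9, 7)
        for k in taps1:  # eval mode: bit-for-bit reproducible
            np.testing.assert_array_equal(taps1[k], taps2[k])

    def test_unknown_tap_is_an_error(self):
        net = FusionNetwork(ModelConfig(d_b=3, d_p=3, d_h=2, d_model=4,
                                        n_layers=0, n_heads=1))
        with pytest.raises(ValueError, match="unknown tap"):
            net.export_hidden_states(np.zeros((2, 3)), np.zeros((2, 3)),
                                     taps=("nope",))
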