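"""LSTM cell, bidirectional unrolling and attention against straight-line oracles."""

import numpy as np
import pytest

from migcn.autodiff import Tensor
from migcn.extractor import (
    AttentionParams,
    CellState,
    ExtractorConfig,
    FeatureExtractor,
    LSTMParams,
    attention_pool,
    bilstm_forward,
    extract_features,
    lstm_step,
    train_extractor,
)
from migcn.layers import param


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _random_lstm_params(rng, n_in, n_cell):
    mats = [param(rng.normal(size=(n_in, n_cell))) for _ in range(4)]
    hmats = [param(rng.normal(size=(n_cell, n_cell))) for _ in range(4)]
    biases = [param(rng.normal(size=n_cell)) for _ in range(4)]
    return LSTMParams(*mats, *hmats, *biases)


def _oracle_step(x, h, c, p):
    """Literal gate-by-gate evaluation of the LSTM update equations."""
    i = _sigmoid(x @ p.W_xi.data + h @ p.W_hi.data + p.b_i.data)
    f = _sigmoid(x @ p.W_xf.data + h @ p.W_hf.data + p.b_f.data)
    o = _sigmoid(x @ p.W_xo.data + h @ p.W_ho.data + p.b_o.data)
    g = np.tanh(x @ p.W_xg.data + h @ p.W_hg.data + p.b_g.data)
    c_new = f * c + i * g
    h_new = o * np.tanh(c_new)
    return h_new, c_new


class TestLstmStep:
    def test_all_zero_parameters_give_half_gates_and_zero_state(self):
        p = LSTMParams(
            *[param(np.zeros((2, 3))) for _ in range(4)],
            *[param(np.zeros((3, 3))) for _ in range(4)],
            *[param(np.zeros(3)) for _ in range(4)],
        )
        state, y = lstm_step(np.zeros(2), CellState.zeros(1, 3), p)
        assert np.allclose(state.c.data, 0.0)
        assert np.allclose(y.data, 0.0)

    def test_unit_prior_cell_scalar_hand_value(self):
        p = LSTMParams(
            *[param(np.zeros((2, 1))) for _ in range(4)],
            *[param(np.zeros((1, 1))) for _ in range(4)],
            *[param(np.zeros(1)) for _ in range(4)],
        )
        prev = CellState(Tensor(np.ones((1, 1))), Tensor(np.zeros((1, 1))))
        state, y = lstm_step(np.zeros(2), prev, p)
        assert np.allclose(state.c.data, 0.5)  # f*1 + i*0 = 0.5
        assert np.allclose(y.data, 0.5 * np.tanh(0.5))

    def test_random_cell_matches_straight_line_oracle(self):
        rng = np.random.default_rng(0)
        p = _random_lstm_params(rng, 4, 3)
        h0, c0 = rng.normal(size=(1, 3)), rng.normal(size=(1, 3))
        x = rng.normal(size=(1, 4))
        state, y = lstm_step(x, CellState(Tensor(c0), Tensor(h0)), p)
        h_ref, c_ref = _oracle_step(x, h0, c0, p)
        assert np.abs(state.c.data - c_ref).max() < 1e-12
        assert np.abs(y.data - h_ref).max() < 1e-12

    def test_short_term_state_bounded_by_one(self):
        rng = np.random.default_rng(1)
        p = _random_lstm_params(rng, 4, 3)
        state = CellState.zeros(1, 3)
        for t in range(20):
            state, y = lstm_step(rng.normal(size=(1, 4)) * 5, state, p)
            assert np.abs(y.data).max() < 1.0

    def test_non_finite_input_rejected(self):
        rng = np.random.default_rng(2)
        p = _random_lstm_params(rng, 2, 2)
        with pytest.raises(ValueError):
            lstm_step(np.array([np.nan, 0.0]), CellState.zeros(1, 2), p)


class TestBilstm:
    def test_constant_sequence_with_shared_params_is_mirror_symmetric(self):
        # on a time-constant input with shared parameters the backward half
        # is the forward half read in reversed time order: both cells see
        # the same prefix lengths, just from opposite ends
        rng = np.random.default_rng(3)
        p = _random_lstm_params(rng, 3, 2)
        x = np.tile(rng.normal(size=(1, 1, 3)), (1, 5, 1))
        ys = bilstm_forward(x, p, p)
        T = len(ys)
        for t in range(T):
            assert np.allclose(ys[t].data[:, :2], ys[T - 1 - t].data[:, 2:])
        # at the midpoint of an odd-length sequence the halves coincide
        assert np.allclose(ys[2].data[:, :2], ys[2].data[:, 2:])

    def test_single_step_is_concatenation_of_two_steps(self):
        rng = np.random.default_rng(4)
        pf, pb = _random_lstm_params(rng, 3, 2), _random_lstm_params(rng, 3, 2)
        x = rng.normal(size=(1, 1, 3))
        ys = bilstm_forward(x, pf, pb)
        _, yf = lstm_step(x[:, 0], CellState.zeros(1, 2), pf)
        _, yb = lstm_step(x[:, 0], CellState.zeros(1, 2), pb)
        assert np.allclose(ys[0].data, np.concatenate([yf.data, yb.data], axis=1))

    def test_random_sequence_matches_unrolled_oracle(self):
        rng = np.random.default_rng(5)
        pf, pb = _random_lstm_params(rng, 4, 3), _random_lstm_params(rng, 4, 3)
        x = rng.normal(size=(2, 5, 4))
        ys = bilstm_forward(x, pf, pb)

        def unroll(p, seq):
            h = np.zeros((2, 3))
            c = np.zeros((2, 3))
            out = []
            for t in range(seq.shape[1]):
                h, c = _oracle_step(seq[:, t], h, c, p)
                out.append(h)
            return out

        fwd = unroll(pf, x)
        bwd = unroll(pb, x[:, ::-1])[::-1]
        for t in range(5):
            ref = np.concatenate([fwd[t], bwd[t]], axis=1)
            assert np.abs(ys[t].data - ref).max() < 1e-10

    def test_cell_size_mismatch_raises(self):
        rng = np.random.default_rng(6)
        pf, pb = _random_lstm_params(rng, 3, 2), _random_lstm_params(rng, 3, 4)
        with pytest.raises(ValueError):
            bilstm_forward(rng.normal(size=(1, 2, 3)), pf, pb)


class TestAttention:
    def _params(self, rng, in_size=4, att=3):
        return AttentionParams(
            param(rng.normal(size=(in_size, att))),
            param(rng.normal(size=att)),
            param(rng.normal(size=(att, 1))),
        )

    def test_singleton_sequence(self):
        rng = np.random.default_rng(7)
        a = self._params(rng)
        y = Tensor(rng.normal(size=(2, 4)))
        s, alpha = attention_pool([y], a)
        assert np.allclose(alpha.data, 1.0)
        assert np.allclose(s.data, y.data)

    def test_identical_steps_give_uniform_weights(self):
        rng = np.random.default_rng(8)
        a = self._params(rng)
        y = Tensor(rng.normal(size=(2, 4)))
        s, alpha = attention_pool([y] * 5, a)
        assert np.allclose(alpha.data, 0.2)
        assert np.allclose(s.data, y.data)

    def test_random_input_matches_logsumexp_oracle(self):
        rng = np.random.default_rng(9)
        a = self._params(rng)
        ys = [rng.normal(size=(3, 4)) for _ in range(4)]
        s, alpha = attention_pool([Tensor(y) for y in ys], a)
        scores = np.stack(
            [np.tanh(y @ a.W_w.data + a.b_w.data) @ a.u_w.data[:, 0] for y in ys],
            axis=1,
        )
        shifted = scores - scores.max(axis=1, keepdims=True)
        ref_alpha = np.exp(shifted) / np.exp(shifted).sum(axis=1, keepdims=True)
        ref_s = sum(ref_alpha[:, t : t + 1] * ys[t] for t in range(4))
        assert np.abs(alpha.data - ref_alpha).max() < 1e-10
        assert np.abs(s.data - ref_s).max() < 1e-10

    def test_weights_always_sum_to_one(self):
        rng = np.random.default_rng(10)
        a = self._params(rng)
        for scale in (1e-3, 1.0, 50.0):
            ys = [Tensor(rng.normal(size=(2, 4)) * scale) for _ in range(6)]
            _, alpha = attention_pool(ys, a)
            assert np.abs(alpha.data.sum(axis=1) - 1.0).max() < 1e-6


@pytest.fixture(scope="module")
def tiny_model():
    cfg = ExtractorConfig(
        input_size=8, max_time=8, cell_size=4, attention_size=3, fc_size=5, seed=0
    )
    return FeatureExtractor(cfg)


class TestExtractorHead:

    def test_scores_normalized_and_features_positive(self, tiny_model, rng):
        x = rng.normal(size=(3, 8, 8))
        scores, fc = tiny_model.forward(x, train=False)
        assert np.abs(scores.data.sum(axis=1) - 1.0).max() < 1e-9
        assert np.all(scores.data > 0)
        assert np.all(fc.data > 0)  # softplus range

    def test_eval_mode_is_deterministic(self, tiny_model, rng):
        x = rng.normal(size=(2, 8, 8))
        a, _ = tiny_model.forward(x, train=False)
        b, _ = tiny_model.forward(x, train=False)
        assert np.array_equal(a.data, b.data)

    def test_duplicate_segments_give_identical_feature_rows(self, tiny_model, rng):
        x = rng.normal(size=(1, 8, 8))
        _, fc = tiny_model.forward(np.repeat(x, 3, axis=0), train=False)
        assert np.allclose(fc.data[0], fc.data[1])
        assert np.allclose(fc.data[0], fc.data[2])


class TestTraining:
    def test_zero_learning_rate_freezes_parameters(self, tiny_dataset):
        cfg = ExtractorConfig(
            input_size=8, max_time=64, cell_size=3, attention_size=2, fc_size=4,
            learning_rate=0.0, batch_size=64, epochs=1, seed=0,
        )
        sub = tiny_dataset.subset(np.arange(64))
        model, log = train_extractor(sub, cfg)
        fresh = FeatureExtractor(cfg)
        for a, b in zip(model.parameters(), fresh.parameters()):
            assert np.array_equal(a.data, b.data)

    def test_loss_decreases_on_separable_toy(self, tiny_dataset):
        cfg = ExtractorConfig(
            input_size=8, max_time=64, cell_size=8, attention_size=4, fc_size=8,
            learning_rate=1e-3, batch_size=64, epochs=8, seed=0,
        )
        model, log = train_extractor(tiny_dataset, cfg)
        assert log["loss"][-1] < log["loss"][0]
        assert log["accuracy"][-1] > 0.5

    def test_larger_cell_not_worse_on_noiseless_fixture(self):
        # statistical capacity check: across seeds, a 16-cell model should
        # reach at least the mean training accuracy of a 2-cell model on
        # clean class signals
        from migcn.synth import SynthSpec, generate_dataset

        ds = generate_dataset(
            SynthSpec(n_channels=8, n_trials_per_class=6, snr=1e6, seed=21)
        )
        accs = {}
        for cell in (2, 16):
            runs = []
            for seed in range(3):
                cfg = ExtractorConfig(
                    input_size=8, max_time=64, cell_size=cell, attention_size=4,
                    fc_size=8, learning_rate=1e-3, batch_size=120, epochs=6,
                    seed=seed,
                )
                _, log = train_extractor(ds, cfg)
                runs.append(log["accuracy"][-1])
            accs[cell] = np.mean(runs)
        assert accs[16] >= accs[2] - 0.02

    def test_feature_table_shape_and_repeatability(self, tiny_dataset):
        cfg = ExtractorConfig(
            input_size=8, max_time=64, cell_size=3, attention_size=2, fc_size=4,
            learning_rate=1e-3, batch_size=128, epochs=1, seed=0,
        )
        model, _ = train_extractor(tiny_dataset, cfg)
        t1 = extract_features(tiny_dataset, model)
        t2 = extract_features(tiny_dataset, model)
        assert t1.features.shape == (len(tiny_dataset), 4)
        assert np.array_equal(t1.features, t2.features)
        assert np.all(t1.features > 0)
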