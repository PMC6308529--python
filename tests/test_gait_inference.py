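import numpy as np
import pytest

from gain.gait_inference import (
    GaitLstmRegressor,
    LstmParams,
    _backward_batch,
    _forward_batch,
    _pack,
    init_params,
    load_gait_model,
    lstm_cell_step,
    save_gait_model,
)
from oracles import lstm_reference_step


def _random_params(rng, D, H, O=2, scale=0.5):
    return LstmParams(
        W_f=rng.normal(scale=scale, size=(H, D + H)),
        W_i=rng.normal(scale=scale, size=(H, D + H)),
        W_g=rng.normal(scale=scale, size=(H, D + H)),
        W_o=rng.normal(scale=scale, size=(H, D + H)),
        b_f=rng.normal(scale=scale, size=H),
        b_i=rng.normal(scale=scale, size=H),
        b_g=rng.normal(scale=scale, size=H),
        b_o=rng.normal(scale=scale, size=H),
        W_y=rng.normal(scale=scale, size=(O, H)),
        b_y=rng.normal(scale=scale, size=O),
    )


def _as_weight_dict(p: LstmParams) -> dict:
    return {name: getattr(p, name).tolist()
            for name in ("W_f", "W_i", "W_g", "W_o", "b_f", "b_i", "b_g", "b_o", "W_y", "b_y")}


class TestCellStep:
    def test_all_zero_parameters_emit_zero(self):
        H, D = 4, 3
        p = LstmParams(
            W_f=np.zeros((H, D + H)), W_i=np.zeros((H, D + H)),
            W_g=np.zeros((H, D + H)), W_o=np.zeros((H, D + H)),
            b_f=np.zeros(H), b_i=np.zeros(H), b_g=np.zeros(H), b_o=np.zeros(H),
            W_y=np.zeros((2, H)), b_y=np.zeros(2),
        )
        h, c, y = lstm_cell_step(p, np.ones(D), np.zeros(H), np.zeros(H))
        np.testing.assert_array_equal(y, 0.0)
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_saturated_forget_gate_drops_old_state(self):
        rng = np.random.default_rng(0)
        p = _random_params(rng, 3, 4)
        p.b_f[:] = -50.0  # forget gate pinned at 0
        x = rng.normal(size=3)
        h = rng.normal(size=4)
        c_a = rng.normal(size=4)
        c_b = rng.normal(size=4)
        _, c_next_a, _ = lstm_cell_step(p, x, h, c_a)
        _, c_next_b, _ = lstm_cell_step(p, x, h, c_b)
        np.testing.assert_allclose(c_next_a, c_next_b, atol=1e-12)

    @pytest.mark.parametrize("hidden", [1, 2, 3, 4, 5])
    def test_matches_independent_equation_oracle(self, hidden):
        rng = np.random.default_rng(hidden)
        D = 3
        p = _random_params(rng, D, hidden)
        x = rng.normal(size=D)
        h0 = rng.normal(size=hidden)
        c0 = rng.normal(size=hidden)
        h, c, y = lstm_cell_step(p, x, h0, c0)
        h_ref, c_ref, y_ref = lstm_reference_step(_as_weight_dict(p), x, h0, c0)
        np.testing.assert_allclose(h, h_ref, atol=1e-12)
        np.testing.assert_allclose(c, c_ref, atol=1e-12)
        np.testing.assert_allclose(y, y_ref, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(1)
        p = _random_params(rng, 3, 4)
        with pytest.raises(ValueError):
            lstm_cell_step(p, np.zeros(5), np.zeros(4), np.zeros(4))


class TestBatchedNetwork:
    def test_batched_forward_equals_sequential_cell_steps(self):
        rng = np.random.default_rng(2)
        p = _random_params(rng, 3, 4)
        Wx, Wh, b, _ = _pack(p)
        theta = {"Wx": Wx, "Wh": Wh, "b": b, "Wy": p.W_y, "by": p.b_y}
        X = rng.normal(size=(2, 6, 3))
        Y, _ = _forward_batch(theta, X)
        for batch in range(2):
            h = np.zeros(4)
            c = np.zeros(4)
            for t in range(6):
                h, c, y = lstm_cell_step(p, X[batch, t], h, c)
                np.testing.assert_allclose(Y[batch, t], y, atol=1e-12)

    def test_backward_matches_numerical_gradients(self):
        rng = np.random.default_rng(3)
        p = _random_params(rng, 2, 3, O=2, scale=0.4)
        Wx, Wh, b, _ = _pack(p)
        theta = {"Wx": Wx, "Wh": Wh, "b": b, "Wy": p.W_y.copy(), "by": p.b_y.copy()}
        X = rng.normal(size=(2, 4, 2))
        target = rng.normal(scale=0.5, size=(2, 4, 2))

        def loss(th):
            Y, _ = _forward_batch(th, X)
            return float(np.mean((Y - target) ** 2))

        Y, cache = _forward_batch(theta, X)
        dY = 2.0 * (Y - target) / Y.size
        grads = _backward_batch(theta, cache, dY)
        eps = 1e-6
        for key in theta:
            num = np.zeros_like(theta[key])
            it = np.nditer(theta[key], flags=["multi_index"])
            while not it.finished:
                idx = it.multi_index
                orig = theta[key][idx]
                theta[key][idx] = orig + eps
                up = loss(theta)
                theta[key][idx] = orig - eps
                down = loss(theta)
                theta[key][idx] = orig
                num[idx] = (up - down) / (2 * eps)
                it.iternext()
            np.testing.assert_allclose(grads[key], num, atol=1e-7,
                                       err_msg=f"gradient mismatch in {key}")


def _toy_sequences(rng, n_seq=4, length=120):
    """Sinusoid input whose lagged nonlinear transform is the target."""
    X_parts, y_parts, lengths, groups = [], [], [], []
    for k in range(n_seq):
        t = np.arange(length) / 40.0 + rng.uniform(0, 1)
        theta = 60 + 15 * np.sin(2 * np.pi * t)
        omega = np.gradient(theta) * 40
        X_parts.append(np.column_stack([theta, theta, omega, omega]))
        phi = 40 + 1.2 * (np.roll(theta, 3) - 60)
        y_parts.append(np.column_stack([phi, phi]))
        lengths.append(length)
        groups.append(f"P{k}")
    return np.concatenate(X_parts), np.concatenate(y_parts), lengths, groups


class TestRegressor:
    def test_constant_target_learned_to_half_degree(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(300, 4))
        y = np.full((300, 2), 33.0)
        m = GaitLstmRegressor(hidden_size=8, max_epochs=60, patience=60, random_state=0)
        m.fit(X, y)
        m.reset_state()
        pred = m.predict(X[:100])
        assert np.max(np.abs(pred - 33.0)) < 0.5

    def test_same_seed_gives_identical_loss_trace(self):
        rng = np.random.default_rng(5)
        X, y, lengths, groups = _toy_sequences(rng)
        kw = dict(hidden_size=10, max_epochs=8, patience=8, random_state=3)
        m1 = GaitLstmRegressor(**kw).fit(X, y, lengths=lengths, groups=groups)
        m2 = GaitLstmRegressor(**kw).fit(X, y, lengths=lengths, groups=groups)
        assert m1.loss_trace_ == m2.loss_trace_

    def test_training_loss_decreases(self):
        rng = np.random.default_rng(6)
        X, y, lengths, groups = _toy_sequences(rng)
        m = GaitLstmRegressor(hidden_size=10, max_epochs=80, patience=80, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        trace = np.asarray(m.loss_trace_)
        assert trace[-1] < trace[0] / 3
        # minibatch noise aside, the trend is downward throughout
        assert np.mean(trace[-5:]) < np.mean(trace[:5])

    def test_streaming_equals_batch_prediction(self):
        rng = np.random.default_rng(7)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=2)
        m = GaitLstmRegressor(hidden_size=6, max_epochs=3, patience=3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        stream = X[:80]
        m.reset_state()
        whole = m.predict(stream)
        m.reset_state()
        frame_by_frame = np.vstack([m.predict(stream[t : t + 1]) for t in range(80)])
        np.testing.assert_allclose(whole, frame_by_frame, atol=1e-12)

    def test_reset_state_replays_identically(self):
        rng = np.random.default_rng(8)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=2)
        m = GaitLstmRegressor(hidden_size=6, max_epochs=3, patience=3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        m.reset_state()
        first = m.predict(X[:50])
        m.reset_state()
        second = m.predict(X[:50])
        np.testing.assert_array_equal(first, second)

    def test_prediction_is_causal(self):
        rng = np.random.default_rng(9)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=2)
        m = GaitLstmRegressor(hidden_size=6, max_epochs=3, patience=3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        stream = X[:60].copy()
        m.reset_state()
        base = m.predict(stream)
        perturbed = stream.copy()
        perturbed[40:] += 100.0  # future frames only
        m.reset_state()
        out = m.predict(perturbed)
        np.testing.assert_array_equal(base[:40], out[:40])

    def test_scaled_predictions_inside_open_unit_interval(self):
        rng = np.random.default_rng(10)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=2)
        m = GaitLstmRegressor(hidden_size=6, max_epochs=3, patience=3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        m.reset_state()
        scaled = m.predict(X[:100], degrees=False)
        assert np.all(np.abs(scaled) < 1.0)

    def test_serialization_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=2)
        m = GaitLstmRegressor(hidden_size=6, max_epochs=3, patience=3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        path = tmp_path / "model.json"
        save_gait_model(m, path)
        back = load_gait_model(path)
        m.reset_state()
        back.reset_state()
        np.testing.assert_allclose(m.predict(X[:40]), back.predict(X[:40]), atol=1e-12)

    def test_learns_lagged_nonlinear_coupling(self):
        rng = np.random.default_rng(12)
        X, y, lengths, groups = _toy_sequences(rng, n_seq=5, length=300)
        m = GaitLstmRegressor(hidden_size=16, max_epochs=120, patience=120,
                              learning_rate=5e-3, random_state=0)
        m.fit(X, y, lengths=lengths, groups=groups)
        m.reset_state()
        pred = m.predict(X[:300])
        assert np.abs(pred[30:] - y[:300][30:]).mean() < 3.0

    def test_too_short_sequences_rejected(self):
        m = GaitLstmRegressor(chunk_length=15)
        with pytest.raises(ValueError, match="chunk_length"):
            m.fit(np.zeros((10, 4)), np.zeros((10, 2)))

    def test_sklearn_get_set_params(self):
        m = GaitLstmRegressor(hidden_size=12)
        assert m.get_params()["hidden_size"] == 12
        m.set_params(hidden_size=7)
        assert m.hidden_size == 7


def test_init_params_shapes_consistent():
    rng = np.random.default_rng(13)
    p = init_params(4, 50, 2, rng)
    assert p.hidden_size == 50
    assert p.input_dim == 4
    assert p.output_dim == 2
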