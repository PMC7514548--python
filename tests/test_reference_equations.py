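"""Reference recurrent/convolutional primitives against independent transcriptions.

The oracles here are deliberately naive, loop-based re-derivations of each
defining equation, written without reference to the package internals.
"""

import numpy as np
import pytest

from capscore.networks.reference import (
    GateParams, RecurrentState, batch_norm, conv1d, dense, global_average_pool,
    gru_step, lstm_step, pool, sigmoid, softmax,
)


def _sig(x):
    return 1.0 / (1.0 + np.exp(-x))


def _random_gates(rng, gates, n_in, n_h):
    return {g: GateParams(W=rng.normal(size=(n_h, n_in)),
                          R=rng.normal(size=(n_h, n_h)),
                          B=rng.normal(size=n_h)) for g in gates}


def oracle_lstm(x, h, c, p):
    """Straight-line transcription: gates I/O/F and sigmoid candidate P."""
    i = _sig(p["I"].W @ x + p["I"].R @ h + p["I"].B)
    o = _sig(p["O"].W @ x + p["O"].R @ h + p["O"].B)
    f = _sig(p["F"].W @ x + p["F"].R @ h + p["F"].B)
    cand = _sig(p["P"].W @ x + p["P"].R @ h + p["P"].B)
    c_new = f * c + i * cand
    return o * np.tanh(c_new), c_new


def oracle_gru(x, h, p):
    s = _sig(p["S"].W @ x + p["S"].R @ h + p["S"].B)
    u = _sig(p["U"].W @ x + p["U"].R @ h + p["U"].B)
    m = np.tanh(p["M"].W @ x + p["M"].R @ (s * h) + p["M"].B)
    return (1 - u) * h + u * m


class TestLSTMStep:
    def test_zero_parameter_closed_form(self):
        # all gates sigmoid(0) = 0.5, candidate 0.5, c = 0.25, h = 0.5*tanh(0.25)
        p = {g: GateParams(np.zeros((1, 1)), np.zeros((1, 1)), np.zeros(1))
             for g in "IOFP"}
        out = lstm_step(np.array([3.0]) * 0, RecurrentState(h=[0.0], c=[0.0]), p)
        assert out.c[0] == pytest.approx(0.25, abs=1e-12)
        assert out.h[0] == pytest.approx(0.5 * np.tanh(0.25), abs=1e-12)
        assert out.h[0] == pytest.approx(0.12245, abs=1e-5)

    def test_saturated_gates_zero_cell(self, rng):
        p = _random_gates(rng, "IOFP", 3, 2)
        for g in "IF":
            p[g] = GateParams(p[g].W * 0, p[g].R * 0, np.full(2, -50.0))
        out = lstm_step(rng.normal(size=3),
                        RecurrentState(h=rng.normal(size=2), c=np.ones(2)), p)
        assert np.all(np.abs(out.c) < 1e-15)

    def test_matches_independent_transcription(self, rng):
        for _ in range(100):
            n_in, n_h = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = _random_gates(rng, "IOFP", n_in, n_h)
            x = rng.normal(size=n_in)
            h0, c0 = rng.normal(size=n_h), rng.normal(size=n_h)
            out = lstm_step(x, RecurrentState(h=h0, c=c0), p)
            h_ref, c_ref = oracle_lstm(x, h0, c0, p)
            np.testing.assert_allclose(out.h, h_ref, atol=1e-10)
            np.testing.assert_allclose(out.c, c_ref, atol=1e-10)

    def test_shape_mismatch_rejected(self, rng):
        p = _random_gates(rng, "IOFP", 3, 2)
        with pytest.raises(ValueError):
            lstm_step(rng.normal(size=4),
                      RecurrentState(h=np.zeros(2), c=np.zeros(2)), p)


class TestGRUStep:
    def test_zero_parameter_closed_form(self):
        p = {g: GateParams(np.zeros((2, 3)), np.zeros((2, 2)), np.zeros(2))
             for g in "SUM"}
        h_prev = np.array([0.4, -0.8])
        out = gru_step(np.zeros(3), h_prev, p)
        np.testing.assert_allclose(out, 0.5 * h_prev, atol=1e-12)

    def test_closed_update_gate_is_identity(self, rng):
        p = _random_gates(rng, "SUM", 3, 2)
        p["U"] = GateParams(p["U"].W * 0, p["U"].R * 0, np.full(2, -50.0))
        h_prev = rng.normal(size=2)
        np.testing.assert_allclose(gru_step(rng.normal(size=3), h_prev, p),
                                   h_prev, atol=1e-12)

    def test_matches_independent_transcription(self, rng):
        for _ in range(100):
            n_in, n_h = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            p = _random_gates(rng, "SUM", n_in, n_h)
            x, h0 = rng.normal(size=n_in), rng.normal(size=n_h)
            np.testing.assert_allclose(gru_step(x, h0, p),
                                       oracle_gru(x, h0, p), atol=1e-10)


class TestConv1d:
    def test_identity_kernel(self, rng):
        x = np.abs(rng.normal(size=10))
        out = conv1d(x, [[0.0, 1.0, 0.0]], [0.0], activation="relu")
        np.testing.assert_allclose(out[0], x[1:-1], atol=1e-12)

    def test_cross_correlation_orientation(self):
        out = conv1d([1.0, 2.0, 3.0, 4.0], [[1.0, -1.0]], [0.0])
        np.testing.assert_allclose(out[0], [-1.0, -1.0, -1.0])

    def test_matches_nested_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            k = int(rng.integers(1, n + 1))
            nk = int(rng.integers(1, 4))
            x = rng.normal(size=n)
            kernels = rng.normal(size=(nk, k))
            biases = rng.normal(size=nk)
            expected = np.array([
                [sum(kernels[d, j] * x[i + j] for j in range(k)) + biases[d]
                 for i in range(n - k + 1)]
                for d in range(nk)
            ])
            np.testing.assert_allclose(conv1d(x, kernels, biases), expected,
                                       atol=1e-10)

    def test_long_kernel_rejected(self):
        with pytest.raises(ValueError):
            conv1d([1.0, 2.0], [[1.0, 1.0, 1.0]], [0.0])


class TestPoolNormDense:
    def test_pool_constant_invariant(self):
        x = np.full((2, 9), 3.5)
        for mode in ("max", "average"):
            assert np.all(pool(x, mode, 3) == 3.5)

    @pytest.mark.parametrize("mode,expected", [("max", [3.0, 5.0]),
                                               ("average", [2.0, 3.5])])
    def test_pool_hand_worked(self, mode, expected):
        np.testing.assert_allclose(pool([1.0, 3.0, 2.0, 5.0], mode, 2)[0],
                                   expected)

    def test_global_average_pool(self, rng):
        x = rng.normal(size=(4, 7))
        np.testing.assert_allclose(global_average_pool(x), x.mean(axis=1))

    def test_batch_norm_standardizes(self, rng):
        x = rng.normal(3, 5, size=(2, 400))
        out = batch_norm(x, np.ones(2), np.zeros(2))
        np.testing.assert_allclose(out.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(out.std(axis=1), 1, atol=1e-2)

    def test_batch_norm_affine_law(self, rng):
        x = rng.normal(size=(1, 500))
        out = batch_norm(x, [2.0], [1.0], eps=0.0)
        assert out.mean() == pytest.approx(1.0, abs=1e-9)
        assert out.std() == pytest.approx(2.0, abs=1e-9)

    def test_batch_norm_hand_standardized(self, rng):
        x = rng.normal(size=(3, 20))
        expected = (x - x.mean(1, keepdims=True)) / np.sqrt(
            x.var(1, keepdims=True) + 1e-5)
        np.testing.assert_allclose(batch_norm(x, np.ones(3), np.zeros(3)),
                                   expected, atol=1e-6)

    def test_dense_identity(self, rng):
        x = rng.normal(size=4)
        np.testing.assert_allclose(dense(x, np.eye(4), np.zeros(4)), x)

    def test_dense_matches_matrix_product(self, rng):
        for _ in range(100):
            n_in, n_out = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            W, B = rng.normal(size=(n_out, n_in)), rng.normal(size=n_out)
            x = rng.normal(size=n_in)
            np.testing.assert_allclose(dense(x, W, B, "tanh"),
                                       np.tanh(W @ x + B), atol=1e-10)

    def test_softmax_normalizes_and_shift_invariant(self, rng):
        z = rng.normal(size=6)
        p = softmax(z)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(softmax(z + 17.3), p, atol=1e-9)

    def test_sigmoid_gates_strictly_open(self, rng):
        # strict openness holds throughout the float-representable band
        z = rng.normal(size=1000) * 8
        s = sigmoid(z)
        assert np.all(s > 0) and np.all(s < 1)
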