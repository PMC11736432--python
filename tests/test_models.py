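import numpy as np
import pytest

from wirenet.geometry import place_on_circle
from wirenet.models import (
    SparseRecurrentModel,
    ctrnn_derivative,
    gru_step,
    make_sparse_model,
    readout,
    rk4_step,
    rnn_step,
)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def rnn_params(rng, f, h, mask=None):
    return {
        "U": rng.standard_normal((f, h)),
        "W": rng.standard_normal((h, h)),
        "b": rng.standard_normal(h),
        "mask": np.ones((h, h)) if mask is None else mask,
    }


def gru_params(rng, f, h, mask=None):
    p = {"mask": np.ones((h, h)) if mask is None else mask}
    for g in ("R", "Q", "S"):
        p[f"W_{g}"] = rng.standard_normal((f, h))
        p[f"U_{g}"] = rng.standard_normal((h, h))
        p[f"b_{g}"] = rng.standard_normal(h)
    return p


class TestRnnStep:
    def test_all_zero_parameters(self):
        p = {"U": np.zeros((2, 2)), "W": np.zeros((2, 2)), "b": np.zeros(2), "mask": np.ones((2, 2))}
        np.testing.assert_array_equal(rnn_step(np.ones(2), np.ones(2), p), 0.0)

    def test_relu_clips_negatives(self):
        p = {"U": np.eye(2), "W": np.zeros((2, 2)), "b": np.zeros(2), "mask": np.ones((2, 2))}
        np.testing.assert_array_equal(rnn_step(np.zeros(2), np.array([-1.0, 2.0]), p), [0.0, 2.0])

    def test_five_step_recurrence_oracle(self, rng):
        p = rnn_params(rng, 3, 4)
        xs = rng.standard_normal((5, 3))
        h = np.zeros(4)
        for x in xs:
            h = rnn_step(h, x, p)
        # independent hand-rolled loop
        h_ref = np.zeros(4)
        for x in xs:
            h_ref = np.maximum(x @ p["U"] + h_ref @ (p["W"] * p["mask"]) + p["b"], 0.0)
        np.testing.assert_allclose(h, h_ref)


class TestReadout:
    def test_zero_logits(self):
        p = {"V": np.zeros((3, 2)), "c": np.zeros(2)}
        np.testing.assert_allclose(readout(np.ones(3), p, "sigmoid"), 0.5)
        p3 = {"V": np.zeros((3, 3)), "c": np.zeros(3)}
        np.testing.assert_allclose(readout(np.ones(3), p3, "softmax"), 1 / 3)

    def test_sigmoid_formula(self, rng):
        p = {"V": rng.standard_normal((4, 3)), "c": rng.standard_normal(3)}
        h = rng.standard_normal(4)
        z = h @ p["V"] + p["c"]
        np.testing.assert_allclose(readout(h, p, "sigmoid"), 1 / (1 + np.exp(-z)))

    def test_softmax_sums_to_one(self, rng):
        p = {"V": rng.standard_normal((4, 5)), "c": rng.standard_normal(5)}
        out = readout(rng.standard_normal(4), p, "softmax")
        assert out.sum() == pytest.approx(1.0)

    def test_unknown_head(self):
        with pytest.raises(ValueError):
            readout(np.zeros(2), {"V": np.zeros((2, 2)), "c": np.zeros(2)}, "relu")


class TestCtrnnDerivative:
    def test_pure_leak(self):
        p = {"U": np.zeros((1, 1)), "W": np.zeros((1, 1)), "b": np.zeros(1), "mask": np.ones((1, 1))}
        np.testing.assert_allclose(
            ctrnn_derivative(np.array([4.0]), np.zeros(1), p, tau=2.0), [-2.0]
        )

    def test_formula_oracle(self, rng):
        p = rnn_params(rng, 3, 4)
        h, x = rng.standard_normal(4), rng.standard_normal(3)
        expected = -h / 1.5 + np.tanh(x @ p["U"] + h @ (p["W"] * p["mask"]) + p["b"])
        np.testing.assert_allclose(ctrnn_derivative(h, x, p, tau=1.5), expected)

    def test_invalid_tau(self):
        p = rnn_params(np.random.default_rng(0), 2, 2)
        with pytest.raises(ValueError):
            ctrnn_derivative(np.zeros(2), np.zeros(2), p, tau=0.0)


class TestRk4:
    def test_zero_derivative(self):
        h = np.array([1.0, -2.0])
        np.testing.assert_array_equal(rk4_step(h, lambda s: np.zeros_like(s), 0.1), h)

    def test_exponential_decay(self):
        h = np.array([1.0])
        for _ in range(10):
            h = rk4_step(h, lambda s: -s, 0.1)
        assert abs(h[0] - np.exp(-1.0)) < 1e-6

    def test_exact_on_constant_derivative(self):
        h = np.array([0.5])
        out = rk4_step(h, lambda s: np.full_like(s, 3.0), 0.25)
        assert out[0] == pytest.approx(0.5 + 3.0 * 0.25)

    def test_fourth_order_convergence(self):
        """Halving dt reduces the global error on dh/dt = -h by ~16x."""

        def err(dt):
            h = np.array([1.0])
            for _ in range(int(round(1.0 / dt))):
                h = rk4_step(h, lambda s: -s, dt)
            return abs(h[0] - np.exp(-1.0))

        ratio = err(0.1) / err(0.05)
        assert 12.0 < ratio < 20.0

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError):
            rk4_step(np.array([np.nan]), lambda s: s, 0.1)


class TestGruStep:
    def test_zero_parameters(self):
        p = gru_params(np.random.default_rng(0), 2, 3)
        for k in p:
            if k != "mask":
                p[k] = np.zeros_like(p[k])
        h = gru_step(np.zeros(3), np.zeros(2), p)
        np.testing.assert_array_equal(h, 0.0)

    def test_saturated_update_gate(self, rng):
        p = gru_params(rng, 2, 3)
        p["b_S"] = np.full(3, 50.0)  # force s ~= 1
        h_prev, x = rng.standard_normal(3), rng.standard_normal(2)
        r = _sigmoid(x @ p["W_R"] + h_prev @ p["U_R"] + p["b_R"])
        h_tilde = np.tanh(x @ p["W_Q"] + (r * h_prev) @ p["U_Q"] + p["b_Q"])
        np.testing.assert_allclose(gru_step(h_prev, x, p), h_tilde, atol=1e-8)

    def test_four_step_recurrence_oracle(self, rng):
        p = gru_params(rng, 3, 4)
        xs = rng.standard_normal((4, 3))
        h = np.zeros(4)
        for x in xs:
            h = gru_step(h, x, p)
        h_ref = np.zeros(4)
        for x in xs:
            r = _sigmoid(x @ p["W_R"] + h_ref @ p["U_R"] + p["b_R"])
            q = np.tanh(x @ p["W_Q"] + (r * h_ref) @ p["U_Q"] + p["b_Q"])
            s = _sigmoid(x @ p["W_S"] + h_ref @ p["U_S"] + p["b_S"])
            h_ref = (1 - s) * h_ref + s * q
        np.testing.assert_allclose(h, h_ref)

    def test_convex_combination_property(self, rng):
        """h' lies componentwise between h and the candidate state."""
        for _ in range(20):
            p = gru_params(rng, 2, 5)
            h_prev, x = rng.standard_normal(5), rng.standard_normal(2)
            r = _sigmoid(x @ p["W_R"] + h_prev @ p["U_R"] + p["b_R"])
            h_tilde = np.tanh(x @ p["W_Q"] + (r * h_prev) @ p["U_Q"] + p["b_Q"])
            h_new = gru_step(h_prev, x, p)
            lo = np.minimum(h_prev, h_tilde) - 1e-12
            hi = np.maximum(h_prev, h_tilde) + 1e-12
            assert np.all((h_new >= lo) & (h_new <= hi))


class TestMaskedCells:
    def test_apply_mask_identity_and_idempotence(self, rng):
        m = make_sparse_model("gru", 3, 10, 2, density=0.3, seed=0)
        before = {k: v.data.copy() for k, v in m.params.items()}
        m.apply_mask()
        for k in before:
            np.testing.assert_array_equal(m.params[k].data, before[k])

    def test_all_zero_mask(self):
        layout = place_on_circle(6, seed=0)
        m = SparseRecurrentModel("rnn", 3, 6, 2, np.zeros((6, 6)), layout, seed=0)
        np.testing.assert_array_equal(m.params["W"].data, 0.0)

    def test_masked_positions_get_zero_gradient(self, rng):
        m = make_sparse_model("gru", 3, 8, 2, density=0.3, seed=1)
        X = rng.uniform(0, 1, (4, 5, 3))
        loss = m.loss(X, np.array([0, 1, 0, 1]))
        loss.backward()
        for name in m.recurrent_param_names:
            off = m.mask == 0
            np.testing.assert_array_equal(m.params[name].grad[off], 0.0)

    @pytest.mark.parametrize("cell", ["rnn", "gru"])
    def test_forward_graph_matches_numpy_steps(self, cell, rng):
        """The autodiff forward pass agrees with the reference step functions."""
        m = make_sparse_model(cell, 3, 6, 2, density=0.5, seed=2)
        X = rng.uniform(0, 1, (2, 4, 3))
        logits = m.forward(X).data

        p = {k: v.data for k, v in m.params.items()}
        p["mask"] = m.mask
        for b in range(2):
            h = np.zeros(6)
            for t in range(4):
                step = rnn_step if cell == "rnn" else gru_step
                h = step(h, X[b, t], p)
            ref = h @ p["V"] + p["c"]
            np.testing.assert_allclose(logits[b], ref, atol=1e-10)

    def test_ctrnn_forward_decays_without_input(self):
        """With f == 0 the cell state relaxes as exp(-t / tau)."""
        layout = place_on_circle(3, seed=0)
        m = SparseRecurrentModel(
            "ctrnn", 2, 3, 2, np.zeros((3, 3)), layout, seed=0, tau=1.0, dt=0.1
        )
        for name in ("U", "b"):
            m.params[name].data[:] = 0.0
        # inject h0 by a single warm-up: instead integrate the derivative fn
        h = np.array([[1.0, 1.0, 1.0]])
        p = {k: v.data for k, v in m.params.items()}
        p["mask"] = m.mask
        for _ in range(10):
            h = rk4_step(h, lambda s: ctrnn_derivative(s, np.zeros((1, 2)), p, 1.0), 0.1)
        np.testing.assert_allclose(h, np.exp(-1.0), rtol=1e-6)

    def test_loss_gradients_match_finite_differences(self, rng):
        m = make_sparse_model("gru", 3, 6, 3, density=0.4, seed=3)
        X = rng.uniform(0, 1, (5, 4, 3))
        y = np.array([0, 1, 2, 0, 1])
        loss = m.loss(X, y)
        loss.backward()
        eps = 1e-6
        for name in ("U_Q", "W_R", "b_S", "V", "c"):
            p = m.params[name]
            flat_idx = np.flatnonzero((p.data != 0) | (p.grad != 0))
            if len(flat_idx) == 0:
                continue
            k = flat_idx[0]
            idx = np.unravel_index(k, p.data.shape)
            p.data[idx] += eps
            up = float(m.loss(X, y).data)
            p.data[idx] -= 2 * eps
            dn = float(m.loss(X, y).data)
            p.data[idx] += eps
            assert p.grad[idx] == pytest.approx((up - dn) / (2 * eps), rel=1e-5, abs=1e-9)
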