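"""Recurrent cells vs scalar-by-scalar evaluations of their printed update
equations, plus stacking and parameter-count closed forms."""

import numpy as np
import pytest

from chirpnet import legendre_memory as lm
from chirpnet import recurrent_cells as rc
from chirpnet import synthetic_audio as sa


def sig(v):
    return 1.0 / (1.0 + np.exp(-v))


def scalar_lstm_step(w, x, h, c, paper=True):
    """Naive per-coordinate evaluation of the LSTM update equations."""
    n = h.size
    h2, c2 = np.zeros(n), np.zeros(n)
    for i in range(n):
        f = sig(w["W_fx"][i] @ x + w["W_fh"][i] @ h + w["b_f"][i])
        g = sig(w["W_ix"][i] @ x + w["W_ih"][i] @ h + w["b_i"][i])
        o = sig(w["W_ox"][i] @ x + w["W_oh"][i] @ h + w["b_o"][i])
        a = w["W_cx"][i] @ x + w["W_ch"][i] @ h + w["b_c"][i]
        ct = sig(a) if paper else np.tanh(a)
        c2[i] = f * c[i] + g * ct
        h2[i] = o * np.tanh(c2[i])
    return h2, c2


def scalar_gru_step(w, x, h):
    n = h.size
    h2 = np.zeros(n)
    for i in range(n):
        z = sig(w["W_zx"][i] @ x + w["W_zh"][i] @ h + w["b_z"][i])
        r_vec = np.array([sig(w["W_rx"][j] @ x + w["W_rh"][j] @ h
                              + w["b_r"][j]) for j in range(n)])
        ht = np.tanh(w["W_cx"][i] @ x + w["W_ch"][i] @ (r_vec * h)
                     + w["b_h"][i])
        h2[i] = (1 - z) * h[i] + z * ht
    return h2


def scalar_lmu_step(w, sys_, x, h, m):
    u = float(w["e_x"] @ x + w["e_h"] @ h + w["e_m"] @ m)
    d, n = m.size, h.size
    m2 = np.zeros(d)
    for i in range(d):
        m2[i] = sys_.Abar[i] @ m + sys_.Bbar[i] * u
    h2 = np.zeros(n)
    for i in range(n):
        h2[i] = np.tanh(w["W_x"][i] @ x + w["W_h"][i] @ h + w["W_m"][i] @ m2)
    return h2, m2


class TestLSTM:
    def test_zero_parameters_paper_mode(self):
        cell = rc.LSTMCell(3, 4, seed=0)
        for v in cell.weights.values():
            v[...] = 0
        h, c = cell.zero_state()
        h2, c2 = rc.lstm_step(cell, np.zeros(3), h, c)
        np.testing.assert_allclose(c2, 0.25)
        np.testing.assert_allclose(h2, 0.5 * np.tanh(0.25))

    def test_saturated_gates_pass_memory_through(self):
        cell = rc.LSTMCell(2, 3, seed=0)
        for v in cell.weights.values():
            v[...] = 0
        cell.weights["b_f"][...] = 50.0   # forget gate open
        cell.weights["b_i"][...] = -50.0  # input gate shut
        c = np.array([0.3, -0.7, 1.2])
        _, c2 = rc.lstm_step(cell, np.ones(2), np.zeros(3), c)
        np.testing.assert_allclose(c2, c, atol=1e-12)

    @pytest.mark.parametrize("mode", ["paper", "standard"])
    def test_matches_scalar_oracle(self, mode):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            p, n = rng.integers(1, 6), rng.integers(1, 6)
            cell = rc.LSTMCell(p, n, mode=mode, seed=seed)
            for v in cell.weights.values():
                v[...] = rng.standard_normal(v.shape)
            x = rng.standard_normal(p)
            h = rng.standard_normal(n)
            c = rng.standard_normal(n)
            h2, c2 = rc.lstm_step(cell, x, h, c)
            eh, ec = scalar_lstm_step(cell.weights, x, h, c,
                                      paper=(mode == "paper"))
            np.testing.assert_allclose(h2, eh, atol=1e-12)
            np.testing.assert_allclose(c2, ec, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        cell = rc.LSTMCell(3, 4)
        with pytest.raises(sa.ValidationError):
            rc.lstm_step(cell, np.zeros(2), *cell.zero_state())


class TestGRU:
    def test_zero_parameters_halves_state(self):
        cell = rc.GRUCell(3, 4, seed=0)
        for v in cell.weights.values():
            v[...] = 0
        h = np.array([0.2, -0.4, 1.0, 0.0])
        np.testing.assert_allclose(rc.gru_step(cell, np.zeros(3), h), 0.5 * h)

    def test_closed_update_gate_freezes_state(self):
        cell = rc.GRUCell(2, 3, seed=1)
        cell.weights["b_z"][...] = -50.0
        h = np.array([0.5, -0.5, 0.1])
        np.testing.assert_allclose(rc.gru_step(cell, np.ones(2), h), h,
                                   atol=1e-12)

    def test_matches_scalar_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            p, n = rng.integers(1, 6), rng.integers(1, 6)
            cell = rc.GRUCell(p, n, seed=seed)
            for v in cell.weights.values():
                v[...] = rng.standard_normal(v.shape)
            x, h = rng.standard_normal(p), rng.standard_normal(n)
            np.testing.assert_allclose(rc.gru_step(cell, x, h),
                                       scalar_gru_step(cell.weights, x, h),
                                       atol=1e-12)


class TestLMU:
    def test_zero_parameters_zero_everything(self):
        cell = rc.LMUCellParams(3, 4, memory_size=5, theta=8, seed=0)
        for v in cell.weights.values():
            v[...] = 0
        h, m = cell.zero_state()
        h2, m2 = rc.lmu_step(cell, np.ones(3), h, m)
        assert np.all(h2 == 0.0) and np.all(m2 == 0.0)

    def test_hand_arithmetic_euler(self):
        """n=1, d=1, e_x=1, Euler at dt/theta = 0.1: unit input writes
        Bbar = 0.1 into the empty memory."""
        cell = rc.LMUCellParams(1, 1, memory_size=1, seed=0)
        cell.system = lm.discretize(lm.build_system(1, theta=1.0), dt=0.1,
                                    method="euler")
        for v in cell.weights.values():
            v[...] = 0
        cell.weights["e_x"][...] = 1.0
        _, m2 = rc.lmu_step(cell, np.array([1.0]), *cell.zero_state())
        np.testing.assert_allclose(m2, [0.1], atol=1e-15)

    def test_matches_scalar_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(2000 + seed)
            p, n, d = rng.integers(1, 6), rng.integers(1, 6), rng.integers(1, 6)
            cell = rc.LMUCellParams(p, n, memory_size=d, theta=10, seed=seed)
            for v in cell.weights.values():
                v[...] = rng.standard_normal(v.shape)
            x = rng.standard_normal(p)
            h = rng.standard_normal(n)
            m = rng.standard_normal(d)
            h2, m2 = rc.lmu_step(cell, x, h, m)
            eh, em = scalar_lmu_step(cell.weights, cell.system, x, h, m)
            np.testing.assert_allclose(h2, eh, atol=1e-12)
            np.testing.assert_allclose(m2, em, atol=1e-12)

    def test_passthrough_memory_reproduces_recursion(self):
        """With e_x = 1 on a scalar input and all other encoders zero, the
        cell's memory over a probe sequence equals run_recursive exactly."""
        n_steps, d = 32, 8
        probe = sa.make_memory_probe("double_pulse", n_steps)
        sys_ = lm.default_system(d, n_steps=n_steps)
        cell = rc.LMUCellParams(1, 2, memory_size=d, seed=0)
        cell.system = sys_
        cell.weights["e_x"][...] = 1.0
        cell.weights["e_h"][...] = 0.0
        cell.weights["e_m"][...] = 0.0
        h, m = cell.zero_state()
        trace = np.zeros((d, n_steps))
        for t in range(n_steps):
            h, m = rc.lmu_step(cell, np.array([probe[t]]), h, m)
            trace[:, t] = m
        ref = lm.run_recursive(sys_, probe).coeffs
        np.testing.assert_array_equal(trace, ref)


class TestStacks:
    def test_single_step_sequence_sum(self):
        stack = rc.make_stack("gru", 3, 4, 1, seed=0)
        outs, summed = rc.run_sequence(stack, np.ones((1, 3)))
        np.testing.assert_array_equal(outs[0], summed)

    def test_zero_input_zero_parameter_outputs(self):
        stack = rc.make_stack("gru", 3, 4, 2, seed=0)
        for cell in stack.cells:
            for v in cell.weights.values():
                v[...] = 0
        outs, summed = rc.run_sequence(stack, np.zeros((5, 3)))
        assert np.all(outs == 0.0) and np.all(summed == 0.0)

    def test_two_layer_equals_manual_composition(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((7, 3))
        stack = rc.make_stack("gru", 3, 4, 2, seed=5)
        outs, _ = rc.run_sequence(stack, X)
        lower = rc.RNNStack(cells=[stack.cells[0]])
        upper = rc.RNNStack(cells=[stack.cells[1]])
        mid, _ = rc.run_sequence(lower, X)
        expect, _ = rc.run_sequence(upper, mid)
        np.testing.assert_allclose(outs, expect, atol=1e-12)

    def test_gru_lmu_combo_ordering(self):
        stack = rc.make_stack("gru+lmu", 3, 4, 2, memory_size=6, seed=0)
        assert isinstance(stack.cells[0], rc.GRUCell)
        assert isinstance(stack.cells[1], rc.LMUCellParams)
        with pytest.raises(sa.ValidationError):
            rc.make_stack("gru+lmu", 3, 4, 1)

    def test_seeded_initialization_deterministic(self):
        a = rc.make_stack("lstm", 3, 4, 2, seed=9)
        b = rc.make_stack("lstm", 3, 4, 2, seed=9)
        for ca, cb in zip(a.cells, b.cells):
            for k in ca.weights:
                np.testing.assert_array_equal(ca.weights[k], cb.weights[k])


class TestParameterCounts:
    @pytest.mark.parametrize("p,n", [(4, 3), (256, 128)])
    def test_closed_forms(self, p, n):
        d = min(n, 5)
        assert rc.trainable_parameter_count(rc.LSTMCell(p, n)) \
            == 4 * (p * n + n * n + n)
        assert rc.trainable_parameter_count(rc.GRUCell(p, n)) \
            == 3 * (p * n + n * n + n)
        assert rc.trainable_parameter_count(
            rc.LMUCellParams(p, n, memory_size=d)) \
            == p * n + n * n + d * n + p + n + d

    def test_parameter_economy_ordering(self):
        """LMU < GRU < LSTM at equal input/hidden sizes with d <= n."""
        for p, n, d in [(256, 128, 64), (1024, 512, 64), (16, 8, 8)]:
            lmu = rc.trainable_parameter_count(
                rc.LMUCellParams(p, n, memory_size=d))
            gru = rc.trainable_parameter_count(rc.GRUCell(p, n))
            lstm = rc.trainable_parameter_count(rc.LSTMCell(p, n))
            assert lmu < gru < lstm


def test_gate_outputs_in_unit_interval():
    rng = np.random.default_rng(0)
    cell = rc.GRUCell(4, 6, seed=3)
    h = cell.zero_state()
    for t in range(20):
        h = rc.gru_step(cell, rng.standard_normal(4) * 5, h)
    lcell = rc.LMUCellParams(4, 6, memory_size=4, theta=20, seed=3)
    hh, m = lcell.zero_state()
    for t in range(20):
        hh, m = rc.lmu_step(lcell, rng.standard_normal(4) * 5, hh, m)
    assert np.all(np.abs(hh) < 1.0)  # tanh range
    assert np.all(np.abs(h) < 1.0)
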