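"""From-scratch recurrent units: LSTM, GRU and the Legendre Memory Unit.

Each cell stores its weights under the names used in its printed update
equations and exposes a pure step function, so a scalar-by-scalar evaluation
of the equations is a valid independent oracle.  Conventions:

* LSTM: gates f, i, o and candidate c~ each have one input kernel, one
  recurrent kernel and one bias.  In ``mode="paper"`` the candidate passes
  through the logistic sigma (as printed); ``mode="standard"`` substitutes
  the conventional tanh candidate.
* GRU: gates z, r and candidate h~ with a single bias per gate; the reset
  gate multiplies the previous hidden state inside the candidate's recurrent
  term.
* LMU: a scalar drive ``u_t = e_x.x_t + e_h.h_{t-1} + e_m.m_{t-1}`` feeds the
  fixed (non-trainable) memory system ``m_t = Abar m_{t-1} + Bbar u_t``; the
  hidden state is ``h_t = tanh(W_x x_t + W_h h_{t-1} + W_m m_t)`` — memory is
  updated first, then the hidden state reads the fresh memory, following the
  original delay-network construction.  Abar, Bbar never count as trainable.

Batched inputs: step functions accept ``x`` of shape (p,) or (batch, p) and
states shaped accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .legendre_memory import StateSpaceSystem, default_system
from .synthetic_audio import ValidationError


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _xavier(rng, fan_out, fan_in, dtype):
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_out, fan_in)).astype(dtype)


def _matvec(W, x):
    # x: (p,) or (batch, p) -> (n,) or (batch, n)
    return x @ W.T


# ---------------------------------------------------------------------------
# LSTM


@dataclass
class LSTMCell:
    input_size: int
    hidden_size: int
    mode: str = "paper"  # "paper": sigma candidate; "standard": tanh
    seed: int = 0
    dtype: type = np.float64
    weights: dict = field(init=False)

    def __post_init__(self) -> None:
        if self.mode not in ("paper", "standard"):
            raise ValidationError("mode must be 'paper' or 'standard'")
        rng = np.random.default_rng(self.seed)
        p, n, dt = self.input_size, self.hidden_size, self.dtype
        self.weights = {}
        for g in "fioc":
            self.weights[f"W_{g}x"] = _xavier(rng, n, p, dt)
            self.weights[f"W_{g}h"] = _xavier(rng, n, n, dt)
            self.weights[f"b_{g}"] = np.zeros(n, dt)

    def zero_state(self, batch=None):
        shape = (self.hidden_size,) if batch is None else (batch, self.hidden_size)
        return np.zeros(shape, self.dtype), np.zeros(shape, self.dtype)

    def trainable_arrays(self):
        return self.weights


def lstm_step(cell: LSTMCell, x, h, c, with_cache: bool = False):
    """One LSTM update; returns (h', c') and optionally the gate cache."""
    w = cell.weights
    x = np.asarray(x, cell.dtype)
    if x.shape[-1] != cell.input_size or h.shape[-1] != cell.hidden_size:
        raise ValidationError("shape mismatch in lstm_step")
    f = sigmoid(_matvec(w["W_fx"], x) + _matvec(w["W_fh"], h) + w["b_f"])
    i = sigmoid(_matvec(w["W_ix"], x) + _matvec(w["W_ih"], h) + w["b_i"])
    o = sigmoid(_matvec(w["W_ox"], x) + _matvec(w["W_oh"], h) + w["b_o"])
    a = _matvec(w["W_cx"], x) + _matvec(w["W_ch"], h) + w["b_c"]
    c_tilde = sigmoid(a) if cell.mode == "paper" else np.tanh(a)
    c_new = f * c + i * c_tilde
    h_new = o * np.tanh(c_new)
    if with_cache:
        return h_new, c_new, dict(x=x, h=h, c=c, f=f, i=i, o=o, a=a,
                                  c_tilde=c_tilde, c_new=c_new)
    return h_new, c_new


# ---------------------------------------------------------------------------
# GRU


@dataclass
class GRUCell:
    input_size: int
    hidden_size: int
    seed: int = 0
    dtype: type = np.float64
    weights: dict = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        p, n, dt = self.input_size, self.hidden_size, self.dtype
        self.weights = {
            "W_zx": _xavier(rng, n, p, dt), "W_zh": _xavier(rng, n, n, dt),
            "b_z": np.zeros(n, dt),
            "W_rx": _xavier(rng, n, p, dt), "W_rh": _xavier(rng, n, n, dt),
            "b_r": np.zeros(n, dt),
            "W_cx": _xavier(rng, n, p, dt), "W_ch": _xavier(rng, n, n, dt),
            "b_h": np.zeros(n, dt),
        }

    def zero_state(self, batch=None):
        shape = (self.hidden_size,) if batch is None else (batch, self.hidden_size)
        return np.zeros(shape, self.dtype)

    def trainable_arrays(self):
        return self.weights


def gru_step(cell: GRUCell, x, h, with_cache: bool = False):
    """One GRU update: h' = (1-z) ⊙ h + z ⊙ h~."""
    w = cell.weights
    x = np.asarray(x, cell.dtype)
    if x.shape[-1] != cell.input_size or h.shape[-1] != cell.hidden_size:
        raise ValidationError("shape mismatch in gru_step")
    z = sigmoid(_matvec(w["W_zx"], x) + _matvec(w["W_zh"], h) + w["b_z"])
    r = sigmoid(_matvec(w["W_rx"], x) + _matvec(w["W_rh"], h) + w["b_r"])
    rh = r * h
    h_tilde = np.tanh(_matvec(w["W_cx"], x) + _matvec(w["W_ch"], rh) + w["b_h"])
    h_new = (1 - z) * h + z * h_tilde
    if with_cache:
        return h_new, dict(x=x, h=h, z=z, r=r, rh=rh, h_tilde=h_tilde)
    return h_new


# ---------------------------------------------------------------------------
# LMU


@dataclass
class LMUCellParams:
    input_size: int
    hidden_size: int
    memory_size: int = 64
    theta: float | None = None  # None -> set from sequence length at run time
    seed: int = 0
    dtype: type = np.float64
    system: StateSpaceSystem | None = None
    weights: dict = field(init=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        p, n, d, dt = (self.input_size, self.hidden_size, self.memory_size,
                       self.dtype)
        if self.system is None:
            n_steps = self.theta if self.theta is not None else 26
            self.system = default_system(d, n_steps=int(n_steps))
        # kernels Xavier; encoders: e_x uniform-scaled, e_h = e_m = 0 at init
        self.weights = {
            "W_x": _xavier(rng, n, p, dt),
            "W_h": _xavier(rng, n, n, dt),
            "W_m": _xavier(rng, n, d, dt),
            "e_x": (rng.uniform(-1, 1, size=p) / np.sqrt(p)).astype(dt),
            "e_h": np.zeros(n, dt),
            "e_m": np.zeros(d, dt),
        }

    def zero_state(self, batch=None):
        hs = (self.hidden_size,) if batch is None else (batch, self.hidden_size)
        ms = (self.memory_size,) if batch is None else (batch, self.memory_size)
        return np.zeros(hs, self.dtype), np.zeros(ms, self.dtype)

    def trainable_arrays(self):
        # Abar/Bbar are fixed: never reported as trainable
        return self.weights


def lmu_step(cell: LMUCellParams, x, h, m, with_cache: bool = False):
    """One LMU update: scalar drive u from (x, h, m), memory first, then
    hidden state from the fresh memory."""
    w = cell.weights
    x = np.asarray(x, cell.dtype)
    if x.shape[-1] != cell.input_size or h.shape[-1] != cell.hidden_size \
            or m.shape[-1] != cell.memory_size:
        raise ValidationError("shape mismatch in lmu_step")
    u = x @ w["e_x"] + h @ w["e_h"] + m @ w["e_m"]  # scalar per batch row
    sys_ = cell.system
    m_new = m @ sys_.Abar.T + np.multiply.outer(u, sys_.Bbar)
    h_new = np.tanh(_matvec(w["W_x"], x) + _matvec(w["W_h"], h)
                    + _matvec(w["W_m"], m_new))
    if with_cache:
        return h_new, m_new, dict(x=x, h=h, m=m, u=u, m_new=m_new, h_new=h_new)
    return h_new, m_new


# ---------------------------------------------------------------------------
# stacking and sequence running


@dataclass
class RNNStack:
    """Homogeneous multi-layer stack, or the GRU-then-LMU combination."""

    cells: list

    def __post_init__(self) -> None:
        for lower, upper in zip(self.cells, self.cells[1:]):
            if upper.input_size != lower.hidden_size:
                raise ValidationError(
                    "layer input size must equal previous layer hidden size"
                )


def make_stack(kind: str, input_size: int, hidden_size: int, layers: int,
               memory_size: int = 64, theta: float | None = None,
               seed: int = 0, dtype=np.float64,
               lstm_mode: str = "paper") -> RNNStack:
    """Build an n-layer stack of one cell type, or ``kind='gru+lmu'``
    (GRU layers below a single LMU top layer; needs >= 2 layers)."""
    kind = kind.lower()
    cells = []
    sizes = [input_size] + [hidden_size] * layers
    for k in range(layers):
        cell_seed = seed * 1000 + k
        if kind == "lstm":
            cells.append(LSTMCell(sizes[k], hidden_size, mode=lstm_mode,
                                  seed=cell_seed, dtype=dtype))
        elif kind == "gru":
            cells.append(GRUCell(sizes[k], hidden_size, seed=cell_seed,
                                 dtype=dtype))
        elif kind == "lmu":
            cells.append(LMUCellParams(sizes[k], hidden_size,
                                       memory_size=memory_size, theta=theta,
                                       seed=cell_seed, dtype=dtype))
        elif kind == "gru+lmu":
            if layers < 2:
                raise ValidationError("gru+lmu requires >= 2 layers")
            if k < layers - 1:
                cells.append(GRUCell(sizes[k], hidden_size, seed=cell_seed,
                                     dtype=dtype))
            else:
                cells.append(LMUCellParams(sizes[k], hidden_size,
                                           memory_size=memory_size,
                                           theta=theta, seed=cell_seed,
                                           dtype=dtype))
        else:
            raise ValidationError(f"unknown stack kind {kind!r}")
    return RNNStack(cells=cells)


def _step_any(cell, x, state):
    if isinstance(cell, LSTMCell):
        h, c = state
        h, c = lstm_step(cell, x, h, c)
        return h, (h, c)
    if isinstance(cell, GRUCell):
        h = gru_step(cell, x, state)
        return h, h
    if isinstance(cell, LMUCellParams):
        h, m = state
        h, m = lmu_step(cell, x, h, m)
        return h, (h, m)
    raise ValidationError(f"unknown cell type {type(cell)}")


def _zero_state_any(cell, batch=None):
    if isinstance(cell, GRUCell):
        return cell.zero_state(batch)
    return cell.zero_state(batch)


def run_sequence(stack: RNNStack, inputs: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Run a (T, features) sequence through the stack from zero initial
    states.  Returns the per-step top-layer outputs (T, n) and their sum over
    time (n,) — the summed output is what feeds the classification head."""
    X = np.asarray(inputs)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValidationError("inputs must be (T, features) with T >= 1")
    states = [_zero_state_any(c) for c in stack.cells]
    T = X.shape[0]
    top = np.zeros((T, stack.cells[-1].hidden_size))
    for t in range(T):
        inp = X[t]
        for k, cell in enumerate(stack.cells):
            inp, states[k] = _step_any(cell, inp, states[k])
        top[t] = inp
    return top, top.sum(axis=0)


# ---------------------------------------------------------------------------
# parameter counting


def trainable_parameter_count(obj) -> int:
    """Total trainable entries of a cell or stack (LMU's Abar/Bbar excluded)."""
    if isinstance(obj, RNNStack):
        return sum(trainable_parameter_count(c) for c in obj.cells)
    if hasattr(obj, "trainable_arrays"):
        return int(sum(a.size for a in obj.trainable_arrays().values()))
    raise ValidationError(f"cannot count parameters of {type(obj)}")
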