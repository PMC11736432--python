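"""Masked sparse recurrent cells: RNN, CT-RNN, Neural ODE (RK4), GRU.

All cells share one architecture: a dense learnable input projection, a
single sparse hidden recurrent layer whose hidden-to-hidden matrices are
gated by a binary mask, and a dense learnable readout. The mask encodes
which directed connections i -> j among hidden units exist; it is shared
across all recurrent matrices of a cell (for the GRU: U_R, U_Q, U_S), so
a connection exists or not as a unit.

Module-level step functions (``rnn_step``, ``gru_step``, ...) are plain
numpy reference implementations of one update; the cell classes build the
same computations as autodiff graphs for training. Matrices are stored
input-major (x @ U), with recurrent W[i, j] = weight of connection i -> j.
"""

from __future__ import annotations

import copy

import numpy as np

from ._autograd import Tensor, constant, softmax_cross_entropy
from .geometry import SpatialLayout, place_on_circle
from .wiring_cost import SparseNet

__all__ = [
    "rnn_step",
    "readout",
    "ctrnn_derivative",
    "rk4_step",
    "gru_step",
    "SparseRecurrentModel",
    "make_sparse_model",
    "random_mask",
]


# ---------------------------------------------------------------------------
# Reference step functions (numpy, single update)
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def rnn_step(h_prev, x_t, params) -> np.ndarray:
    """h_t = ReLU(x U + h W + b) with the recurrent matrix masked."""
    W = params["W"] * params["mask"]
    return np.maximum(x_t @ params["U"] + h_prev @ W + params["b"], 0.0)


def readout(h_t, params, head: str = "softmax") -> np.ndarray:
    """Project the hidden state to outputs with a sigmoid or softmax head."""
    z = h_t @ params["V"] + params["c"]
    if head == "sigmoid":
        return _sigmoid(z)
    if head == "softmax":
        z = z - z.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)
    raise ValueError(f"unknown head {head!r}")


def ctrnn_derivative(h, x_t, params, tau: float) -> np.ndarray:
    """dh/dt = -h/tau + tanh(x U + h W + b), recurrent matrix masked."""
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    W = params["W"] * params["mask"]
    return -h / tau + np.tanh(x_t @ params["U"] + h @ W + params["b"])


def rk4_step(state, derivative_fn, dt: float):
    """One classical fourth-order Runge-Kutta update of size dt."""
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    state = np.asarray(state, dtype=np.float64)
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    k1 = derivative_fn(state)
    k2 = derivative_fn(state + 0.5 * dt * k1)
    k3 = derivative_fn(state + 0.5 * dt * k2)
    k4 = derivative_fn(state + dt * k3)
    return state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def gru_step(h_prev, x_t, params) -> np.ndarray:
    """One GRU update; all three recurrent matrices share the mask."""
    mask = params["mask"]
    r = _sigmoid(x_t @ params["W_R"] + h_prev @ (params["U_R"] * mask) + params["b_R"])
    h_tilde = np.tanh(
        x_t @ params["W_Q"] + (r * h_prev) @ (params["U_Q"] * mask) + params["b_Q"]
    )
    s = _sigmoid(x_t @ params["W_S"] + h_prev @ (params["U_S"] * mask) + params["b_S"])
    return (1.0 - s) * h_prev + s * h_tilde


# ---------------------------------------------------------------------------
# Trainable cells
# ---------------------------------------------------------------------------

_RECURRENT_PARAMS = {
    "rnn": ("W",),
    "ctrnn": ("W",),
    "node": ("W",),
    "gru": ("U_R", "U_Q", "U_S"),
}

# Matrix treated as "the" per-connection weight for wiring cost and for
# magnitude/sign-based rewiring decisions (GRU: candidate-state matrix).
_DESIGNATED = {"rnn": "W", "ctrnn": "W", "node": "W", "gru": "U_Q"}


class SparseRecurrentModel:
    """A sparse recurrent classifier over sequences (B, T, F) -> logits (B, O).

    Parameters are held as autodiff tensors; recurrent matrices are
    multiplied by the binary mask inside the forward graph, so masked-out
    positions receive exactly zero gradient. ``apply_mask`` additionally
    zeroes storage so invariants hold after any in-place update.
    """

    def __init__(
        self,
        cell_type: str,
        input_size: int,
        hidden_size: int,
        output_size: int,
        mask: np.ndarray,
        layout: SpatialLayout,
        seed: int = 0,
        tau: float = 1.0,
        dt: float = 0.1,
        interval: float = 1.0,
        input_units: np.ndarray | None = None,
        output_units: np.ndarray | None = None,
    ):
        if cell_type not in _RECURRENT_PARAMS:
            raise ValueError(f"unknown cell_type {cell_type!r}")
        mask = np.asarray(mask, dtype=np.float64)
        if mask.shape != (hidden_size, hidden_size):
            raise ValueError(f"mask must be ({hidden_size}, {hidden_size}), got {mask.shape}")
        if layout.n_units != hidden_size:
            raise ValueError("layout size must match hidden_size")
        if tau <= 0:
            raise ValueError("tau must be > 0")
        if dt <= 0:
            raise ValueError("dt must be > 0")

        self.cell_type = cell_type
        self.input_size = input_size
        self.hidden_size = hidden_size
        self.output_size = output_size
        self.mask = mask
        self.layout = layout
        self.tau = tau
        self.dt = dt
        self.interval = interval
        self.input_units = (
            np.ones(hidden_size) if input_units is None else np.asarray(input_units, float)
        )
        self.output_units = (
            np.ones(hidden_size) if output_units is None else np.asarray(output_units, float)
        )

        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        fan_in_rec = max(1.0, mask.sum() / hidden_size)

        def inp(name):
            w = rng.standard_normal((input_size, hidden_size)) / np.sqrt(input_size)
            self.params[name] = Tensor(w * self.input_units[None, :], requires_grad=True)

        def rec(name):
            w = rng.standard_normal((hidden_size, hidden_size)) / np.sqrt(fan_in_rec)
            self.params[name] = Tensor(w * mask, requires_grad=True)

        def bias(name):
            self.params[name] = Tensor(np.zeros(hidden_size), requires_grad=True)

        if cell_type == "gru":
            for g in ("R", "Q", "S"):
                inp(f"W_{g}"), rec(f"U_{g}"), bias(f"b_{g}")
        else:
            inp("U"), rec("W"), bias("b")
        v = rng.standard_normal((hidden_size, output_size)) / np.sqrt(hidden_size)
        self.params["V"] = Tensor(v * self.output_units[:, None], requires_grad=True)
        self.params["c"] = Tensor(np.zeros(output_size), requires_grad=True)

    # -- mask handling -----------------------------------------------------

    @property
    def recurrent_param_names(self) -> tuple[str, ...]:
        return _RECURRENT_PARAMS[self.cell_type]

    @property
    def designated_recurrent(self) -> str:
        return _DESIGNATED[self.cell_type]

    def apply_mask(self) -> "SparseRecurrentModel":
        """Zero recurrent weights off the mask (idempotent); also enforce
        input/output unit restrictions for bio-instantiated models."""
        for name in self.recurrent_param_names:
            self.params[name].data *= self.mask
        if self.cell_type == "gru":
            inp_names, b_names = ("W_R", "W_Q", "W_S"), ()
        else:
            inp_names, b_names = ("U",), ()
        for name in inp_names:
            self.params[name].data *= self.input_units[None, :]
        self.params["V"].data *= self.output_units[:, None]
        return self

    def set_connectivity(self, mask: np.ndarray, designated_weights: np.ndarray) -> None:
        """Install a rewired mask + designated weight matrix and re-mask."""
        self.mask = np.asarray(mask, dtype=np.float64)
        self.params[self.designated_recurrent].data = np.asarray(
            designated_weights, dtype=np.float64
        ).copy()
        self.apply_mask()

    def to_sparse_net(self) -> SparseNet:
        """Spatial view of the hidden layer used for wiring cost and rewiring."""
        w = self.params[self.designated_recurrent].data * self.mask
        return SparseNet(self.mask.copy(), w.copy(), self.layout)

    def clone(self) -> "SparseRecurrentModel":
        new = copy.copy(self)
        new.mask = self.mask.copy()
        new.params = {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.params.items()}
        new.input_units = self.input_units.copy()
        new.output_units = self.output_units.copy()
        return new

    # -- forward graph -----------------------------------------------------

    def _masked(self, name: str) -> Tensor:
        return self.params[name] * constant(self.mask)

    def forward(self, X: np.ndarray) -> Tensor:
        """Run the sequence batch (B, T, F); return logits at the final step."""
        X = np.asarray(X, dtype=np.float64)
        B, T, F = X.shape
        if F != self.input_size:
            raise ValueError(f"expected {self.input_size} features, got {F}")
        h = constant(np.zeros((B, self.hidden_size)))  # h_0 = 0
        p = self.params
        in_mask = constant(self.input_units[None, :])

        if self.cell_type == "gru":
            U_R, U_Q, U_S = (self._masked(n) for n in ("U_R", "U_Q", "U_S"))
            W_R, W_Q, W_S = (p[n] * in_mask for n in ("W_R", "W_Q", "W_S"))
            for t in range(T):
                x = constant(X[:, t, :])
                r = (x @ W_R + h @ U_R + p["b_R"]).sigmoid()
                h_tilde = (x @ W_Q + (r * h) @ U_Q + p["b_Q"]).tanh()
                s = (x @ W_S + h @ U_S + p["b_S"]).sigmoid()
                h = (1.0 - s) * h + s * h_tilde
        elif self.cell_type == "rnn":
            W = self._masked("W")
            U = p["U"] * in_mask
            for t in range(T):
                x = constant(X[:, t, :])
                h = (x @ U + h @ W + p["b"]).relu()
        else:  # ctrnn / node: RK4 over each observation interval
            W = self._masked("W")
            U = p["U"] * in_mask
            n_sub = max(1, int(round(self.interval / self.dt)))
            dt = self.interval / n_sub
            leak = self.cell_type == "ctrnn"

            for t in range(T):
                x = constant(X[:, t, :])
                drive = x @ U  # input held constant over the interval

                def g(hh):
                    out = (drive + hh @ W + p["b"]).tanh()
                    if leak:
                        out = out - (1.0 / self.tau) * hh
                    return out

                for _ in range(n_sub):
                    k1 = g(h)
                    k2 = g(h + (dt / 2.0) * k1)
                    k3 = g(h + (dt / 2.0) * k2)
                    k4 = g(h + dt * k3)
                    h = h + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

        return h @ (p["V"] * constant(self.output_units[:, None])) + p["c"]

    # -- inference helpers ---------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(X).data, axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def loss(self, X: np.ndarray, y: np.ndarray) -> Tensor:
        return softmax_cross_entropy(self.forward(X), np.asarray(y))


# ---------------------------------------------------------------------------
# Construction helpers
# ---------------------------------------------------------------------------

def random_mask(
    n: int,
    density: float,
    rng: np.random.Generator,
    allow_self: bool = True,
) -> np.ndarray:
    """Binary (n, n) mask with round(density * n_slots) connections."""
    if not 0 < density <= 1:
        raise ValueError("density must be in (0, 1]")
    slots = np.arange(n * n)
    if not allow_self:
        slots = slots[slots // n != slots % n]
    m = int(round(density * slots.size))
    chosen = rng.choice(slots, size=m, replace=False)
    mask = np.zeros(n * n)
    mask[chosen] = 1.0
    return mask.reshape(n, n)


def make_sparse_model(
    cell_type: str,
    input_size: int,
    hidden_size: int,
    output_size: int,
    density: float = 0.1,
    layout: SpatialLayout | None = None,
    seed: int = 0,
    allow_self: bool = True,
    **cell_kwargs,
) -> SparseRecurrentModel:
    """Build a cell with units on a circle and a random mask at given density."""
    rng = np.random.default_rng(seed)
    if layout is None:
        layout = place_on_circle(hidden_size, radius=1.0, seed=seed, mode="random")
    mask = random_mask(hidden_size, density, rng, allow_self=allow_self)
    return SparseRecurrentModel(
        cell_type,
        input_size,
        hidden_size,
        output_size,
        mask,
        layout,
        seed=seed,
        **cell_kwargs,
    )
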