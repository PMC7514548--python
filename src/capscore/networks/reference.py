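"""Reference single-step implementations of the network building blocks.

These functions are deliberately literal, unbatched transcriptions of the
defining equations of each layer — one LSTM/GRU time step, one valid
convolution, one pooling or dense application — and serve as the ground
truth that the vectorized trainable layers are verified against.

Conventions
-----------
* Weight matrices are ``(n_out, n_in)`` so a step computes ``W @ x``.
* The LSTM cell candidate follows the printed defining equation, which uses
  a *sigmoid* nonlinearity; the conventional tanh candidate is available
  via ``candidate="tanh"`` (the trainable network's default, see
  :mod:`capscore.networks.models`).
* The convolution is cross-correlation (no kernel flip), the deep-learning
  convention, with valid (no padding) support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

# ----------------------------------------------------------------------------
# Activations

SELU_ALPHA = 1.6732632423543772
SELU_LAMBDA = 1.0507009873554805


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Logistic function, numerically stable on both tails."""
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(np.asarray(x, dtype=np.float64), 0.0)


def selu(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    return SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * (np.exp(x) - 1.0))


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": lambda x: np.asarray(x, dtype=np.float64),
    "sigmoid": sigmoid,
    "tanh": np.tanh,
    "relu": relu,
    "selu": selu,
    "softmax": softmax,
}


def _resolve_activation(activation) -> Callable[[np.ndarray], np.ndarray]:
    if callable(activation):
        return activation
    try:
        return ACTIVATIONS[activation]
    except KeyError:
        raise ValueError(f"unknown activation {activation!r}") from None


# ----------------------------------------------------------------------------
# Recurrent primitives


@dataclass
class GateParams:
    """Input weights W, recurrent weights R and bias B of one gate/candidate."""

    W: np.ndarray  # (n_hidden, n_input)
    R: np.ndarray  # (n_hidden, n_hidden)
    B: np.ndarray  # (n_hidden,)

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=np.float64))
        self.R = np.atleast_2d(np.asarray(self.R, dtype=np.float64))
        self.B = np.atleast_1d(np.asarray(self.B, dtype=np.float64))
        h = self.W.shape[0]
        if self.R.shape != (h, h) or self.B.shape != (h,):
            raise ValueError(
                f"inconsistent gate shapes: W {self.W.shape}, R {self.R.shape}, "
                f"B {self.B.shape}"
            )

    def pre_activation(self, x: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        return self.W @ x + self.R @ h_prev + self.B


@dataclass
class RecurrentState:
    """Hidden state h (and, for the LSTM, cell state c) after one step."""

    h: np.ndarray
    c: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=np.float64))
        if self.c is not None:
            self.c = np.atleast_1d(np.asarray(self.c, dtype=np.float64))
            if self.c.shape != self.h.shape:
                raise ValueError("h and c must share a shape")
        if not np.all(np.isfinite(self.h)):
            raise ValueError("non-finite hidden state")


def _check_gate_set(params: Mapping[str, GateParams], gates: str, n_in: int) -> int:
    missing = [g for g in gates if g not in params]
    if missing:
        raise ValueError(f"missing gate parameters: {missing}")
    h = params[gates[0]].W.shape[0]
    for g in gates:
        p = params[g]
        if p.W.shape != (h, n_in):
            raise ValueError(
                f"gate {g}: W shape {p.W.shape} inconsistent with input "
                f"size {n_in} and hidden size {h}"
            )
    return h


def lstm_step(x: np.ndarray,
              state: RecurrentState,
              params: Mapping[str, GateParams],
              candidate: str = "sigmoid") -> RecurrentState:
    """One LSTM time step.

    Gates: input ``I``, output ``O`` and forget ``F`` (all sigmoid) plus the
    cell candidate ``P``.  The cell state updates as
    ``c_t = F_t * c_{t-1} + I_t * P_t`` and the hidden state as
    ``h_t = O_t * tanh(c_t)`` (elementwise products throughout).

    Parameters
    ----------
    x : ndarray
        Input vector for this step.
    state : RecurrentState
        Previous hidden and cell state (``c`` must be present).
    params : mapping
        Gate parameters keyed ``"I", "O", "F", "P"``.
    candidate : {"sigmoid", "tanh"}
        Nonlinearity of the cell candidate P.  Default is the sigmoid of
        the defining equations; ``"tanh"`` selects the conventional cell.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    if state.c is None:
        raise ValueError("LSTM state requires a cell vector c")
    _check_gate_set(params, "IOFP", x.shape[0])
    g = _resolve_activation(candidate)
    i_t = sigmoid(params["I"].pre_activation(x, state.h))
    o_t = sigmoid(params["O"].pre_activation(x, state.h))
    f_t = sigmoid(params["F"].pre_activation(x, state.h))
    p_t = g(params["P"].pre_activation(x, state.h))
    c_t = f_t * state.c + i_t * p_t
    h_t = o_t * np.tanh(c_t)
    return RecurrentState(h=h_t, c=c_t)


def gru_step(x: np.ndarray,
             h_prev: np.ndarray,
             params: Mapping[str, GateParams]) -> np.ndarray:
    """One GRU time step.

    Reset gate ``S`` and update gate ``U`` are sigmoid; the candidate
    activation is ``M_t = tanh(W_M x + R_M (S_t * h_{t-1}) + B_M)`` and the
    new hidden state is ``h_t = (1 - U_t) * h_{t-1} + U_t * M_t``.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    h_prev = np.atleast_1d(np.asarray(h_prev, dtype=np.float64))
    _check_gate_set(params, "SUM", x.shape[0])
    s_t = sigmoid(params["S"].pre_activation(x, h_prev))
    u_t = sigmoid(params["U"].pre_activation(x, h_prev))
    m = params["M"]
    m_t = np.tanh(m.W @ x + m.R @ (s_t * h_prev) + m.B)
    return (1.0 - u_t) * h_prev + u_t * m_t


# ----------------------------------------------------------------------------
# Convolutional primitives


def conv1d(x: np.ndarray,
           kernels: np.ndarray,
           biases: np.ndarray,
           activation="linear") -> np.ndarray:
    """Valid cross-correlation of a 1-D series with a bank of kernels.

    Feature map ``d`` is ``activation(K_d (*) x + B_d)`` where ``(*)`` slides
    each kernel over the series without padding, so the output length is
    ``len(x) - len(K_d) + 1``.

    Returns an ``(n_kernels, out_len)`` array.
    """
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    kernels = np.atleast_2d(np.asarray(kernels, dtype=np.float64))
    biases = np.atleast_1d(np.asarray(biases, dtype=np.float64))
    n_k, k_len = kernels.shape
    if k_len > x.shape[0]:
        raise ValueError(f"kernel length {k_len} exceeds input length {x.shape[0]}")
    if biases.shape != (n_k,):
        raise ValueError("one bias per kernel required")
    phi = _resolve_activation(activation)
    out_len = x.shape[0] - k_len + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, k_len)  # (out_len, k)
    maps = windows @ kernels.T + biases  # (out_len, n_k)
    return phi(maps.T)


def pool(features: np.ndarray, mode: str = "max", size: int = 1) -> np.ndarray:
    """Non-overlapping pooling along the temporal (last) axis.

    ``mode="max"`` or ``"average"``; a trailing window shorter than
    ``size`` is dropped.  ``size=None``-like global average pooling is
    exposed via :func:`global_average_pool`.
    """
    if size < 1:
        raise ValueError("pool size must be >= 1")
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    n_ch, length = features.shape
    n_win = length // size
    win = features[:, : n_win * size].reshape(n_ch, n_win, size)
    if mode == "max":
        return win.max(axis=-1)
    if mode in ("average", "avg", "mean"):
        return win.mean(axis=-1)
    raise ValueError(f"unknown pooling mode {mode!r}")


def global_average_pool(features: np.ndarray) -> np.ndarray:
    """Average each channel over the whole temporal axis."""
    return np.atleast_2d(np.asarray(features, dtype=np.float64)).mean(axis=-1)


def batch_norm(features: np.ndarray,
               scale: np.ndarray,
               shift: np.ndarray,
               running_mean: np.ndarray | None = None,
               running_var: np.ndarray | None = None,
               training: bool = True,
               eps: float = 1e-5) -> np.ndarray:
    """Per-channel standardization followed by a learned affine map.

    ``features`` is ``(n_channels, length)``.  In training mode the batch
    statistics of each channel are used; in inference mode the supplied
    running statistics are used instead.
    """
    features = np.atleast_2d(np.asarray(features, dtype=np.float64))
    scale = np.asarray(scale, dtype=np.float64).reshape(-1, 1)
    shift = np.asarray(shift, dtype=np.float64).reshape(-1, 1)
    if scale.shape[0] != features.shape[0]:
        raise ValueError("scale/shift must have one entry per channel")
    if training:
        mu = features.mean(axis=1, keepdims=True)
        var = features.var(axis=1, keepdims=True)
    else:
        if running_mean is None or running_var is None:
            raise ValueError("inference mode requires running statistics")
        mu = np.asarray(running_mean, dtype=np.float64).reshape(-1, 1)
        var = np.asarray(running_var, dtype=np.float64).reshape(-1, 1)
    xhat = (features - mu) / np.sqrt(var + eps)
    return scale * xhat + shift


def dense(x: np.ndarray,
          W: np.ndarray,
          B: np.ndarray,
          activation="linear") -> np.ndarray:
    """Fully connected layer: ``activation(W @ x + B)``."""
    x = np.atleast_1d(np.asarray(x, dtype=np.float64))
    W = np.atleast_2d(np.asarray(W, dtype=np.float64))
    B = np.atleast_1d(np.asarray(B, dtype=np.float64))
    if W.shape[1] != x.shape[0] or B.shape[0] != W.shape[0]:
        raise ValueError(
            f"shape mismatch: W {W.shape}, x {x.shape}, B {B.shape}"
        )
    phi = _resolve_activation(activation)
    return phi(W @ x + B)
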