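"""Trainable NumPy layers with hand-written backpropagation.

Array conventions:

* Recurrent layers take ``(batch, time, features)`` and return either the
  full hidden sequence ``(batch, time, hidden)`` or the last step
  ``(batch, hidden)``.
* Convolutional layers take ``(batch, length, channels)``.
* :class:`Dense` applies to the last axis of any-rank input, so the same
  layer serves both per-timestep heads (sequence-to-sequence) and flat
  classification heads.

Every layer exposes ``forward(x, training)``, ``backward(grad_out)``, and
parallel ``params`` / ``grads`` lists consumed by the optimizer.  Gradients
are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

from .reference import SELU_ALPHA, SELU_LAMBDA, sigmoid


def glorot_uniform(rng: np.random.Generator, n_in: int, n_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grads(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params))


class Activation(Layer):
    """Elementwise nonlinearity (relu, selu, tanh, sigmoid, linear)."""

    def __init__(self, kind: str):
        super().__init__()
        if kind not in ("relu", "selu", "tanh", "sigmoid", "linear"):
            raise ValueError(f"unsupported activation {kind!r}")
        self.kind = kind
        self._cache = None

    def forward(self, x, training=False):
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "selu":
            y = SELU_LAMBDA * np.where(x > 0, x, SELU_ALPHA * (np.exp(x) - 1.0))
        elif self.kind == "tanh":
            y = np.tanh(x)
        elif self.kind == "sigmoid":
            y = sigmoid(x)
        else:
            y = x
        self._cache = (x, y)
        return y

    def backward(self, grad_out):
        x, y = self._cache
        if self.kind == "relu":
            return grad_out * (x > 0)
        if self.kind == "selu":
            return grad_out * np.where(x > 0, SELU_LAMBDA, y + SELU_LAMBDA * SELU_ALPHA)
        if self.kind == "tanh":
            return grad_out * (1.0 - y * y)
        if self.kind == "sigmoid":
            return grad_out * y * (1.0 - y)
        return grad_out


class Dense(Layer):
    """Affine map on the last axis, optionally followed by an activation."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear",
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_out = n_in, n_out
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.act = Activation(activation)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, training=False):
        self._x = x
        y = x @ self.W + self.b
        return self.act.forward(y, training)

    def backward(self, grad_out):
        gz = self.act.backward(grad_out)
        x2 = self._x.reshape(-1, self.n_in)
        gz2 = gz.reshape(-1, self.n_out)
        self.grads[0] += x2.T @ gz2
        self.grads[1] += gz2.sum(axis=0)
        return gz @ self.W.T


class LSTM(Layer):
    """Gated recurrent layer with input/forget/output gates and a cell state.

    ``candidate`` selects the cell-candidate nonlinearity: ``"tanh"`` (the
    conventional, trainable default) or ``"sigmoid"`` (the literal form of
    the reference step in :mod:`capscore.networks.reference`).
    """

    GATES = 4  # I, F, P (candidate), O — packed in that order

    def __init__(self, n_in: int, n_hidden: int, candidate: str = "tanh",
                 return_sequences: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if candidate not in ("tanh", "sigmoid"):
            raise ValueError("candidate must be 'tanh' or 'sigmoid'")
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_hidden = n_in, n_hidden
        self.candidate = candidate
        self.return_sequences = return_sequences
        g = self.GATES
        self.W = glorot_uniform(rng, n_in, n_hidden, (n_in, g * n_hidden))
        self.R = glorot_uniform(rng, n_hidden, n_hidden, (n_hidden, g * n_hidden))
        self.b = np.zeros(g * n_hidden)
        self.b[n_hidden: 2 * n_hidden] = 1.0  # forget-gate bias: remember by default
        self.params = [self.W, self.R, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def _cand(self, z):
        return np.tanh(z) if self.candidate == "tanh" else sigmoid(z)

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            z = x[:, t] @ self.W + h @ self.R + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            p = self._cand(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_new = f * c + i * p
            tc = np.tanh(c_new)
            h_new = o * tc
            cache.append((x[:, t], h, c, i, f, p, o, tc))
            h, c = h_new, c_new
            hs[:, t] = h
        self._cache = (cache, x.shape)
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, grad_out):
        cache, (B, T, D) = self._cache
        H = self.n_hidden
        if self.return_sequences:
            gh_seq = grad_out
        else:
            gh_seq = np.zeros((B, T, H))
            gh_seq[:, -1] = grad_out
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        gW, gR, gb = self.grads
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, p, o, tc = cache[t]
            dh = gh_seq[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            df = dc * c_prev
            di = dc * p
            dp = dc * i
            dc_next = dc * f
            dz = np.empty((B, 4 * H))
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H:2 * H] = df * f * (1.0 - f)
            if self.candidate == "tanh":
                dz[:, 2 * H:3 * H] = dp * (1.0 - p * p)
            else:
                dz[:, 2 * H:3 * H] = dp * p * (1.0 - p)
            dz[:, 3 * H:] = do * o * (1.0 - o)
            gW += x_t.T @ dz
            gR += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.R.T
        return dx


class GRU(Layer):
    """Gated recurrent unit: reset gate S, update gate U, candidate M."""

    def __init__(self, n_in: int, n_hidden: int, return_sequences: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_hidden = n_in, n_hidden
        self.return_sequences = return_sequences
        # S and U packed together; M kept separate because its recurrent
        # path runs through the reset-gated hidden state.
        self.Wg = glorot_uniform(rng, n_in, n_hidden, (n_in, 2 * n_hidden))
        self.Rg = glorot_uniform(rng, n_hidden, n_hidden, (n_hidden, 2 * n_hidden))
        self.bg = np.zeros(2 * n_hidden)
        self.Wm = glorot_uniform(rng, n_in, n_hidden, (n_in, n_hidden))
        self.Rm = glorot_uniform(rng, n_hidden, n_hidden, (n_hidden, n_hidden))
        self.bm = np.zeros(n_hidden)
        self.params = [self.Wg, self.Rg, self.bg, self.Wm, self.Rm, self.bm]
        self.grads = [np.zeros_like(p) for p in self.params]
        self._cache = None

    def forward(self, x, training=False):
        B, T, D = x.shape
        H = self.n_hidden
        h = np.zeros((B, H))
        hs = np.empty((B, T, H))
        cache = []
        for t in range(T):
            zg = x[:, t] @ self.Wg + h @ self.Rg + self.bg
            s = sigmoid(zg[:, :H])
            u = sigmoid(zg[:, H:])
            sh = s * h
            m = np.tanh(x[:, t] @ self.Wm + sh @ self.Rm + self.bm)
            h_new = (1.0 - u) * h + u * m
            cache.append((x[:, t], h, s, u, sh, m))
            h = h_new
            hs[:, t] = h
        self._cache = (cache, x.shape)
        return hs if self.return_sequences else hs[:, -1]

    def backward(self, grad_out):
        cache, (B, T, D) = self._cache
        H = self.n_hidden
        if self.return_sequences:
            gh_seq = grad_out
        else:
            gh_seq = np.zeros((B, T, H))
            gh_seq[:, -1] = grad_out
        dx = np.empty((B, T, D))
        dh_next = np.zeros((B, H))
        gWg, gRg, gbg, gWm, gRm, gbm = self.grads
        for t in range(T - 1, -1, -1):
            x_t, h_prev, s, u, sh, m = cache[t]
            dh = gh_seq[:, t] + dh_next
            du = dh * (m - h_prev)
            dm = dh * u
            dzm = dm * (1.0 - m * m)
            dsh = dzm @ self.Rm.T
            ds = dsh * h_prev
            dzs = ds * s * (1.0 - s)
            dzu = du * u * (1.0 - u)
            dzg = np.concatenate([dzs, dzu], axis=1)
            gWm += x_t.T @ dzm
            gRm += sh.T @ dzm
            gbm += dzm.sum(axis=0)
            gWg += x_t.T @ dzg
            gRg += h_prev.T @ dzg
            gbg += dzg.sum(axis=0)
            dx[:, t] = dzg @ self.Wg.T + dzm @ self.Wm.T
            dh_next = dh * (1.0 - u) + dsh * s + dzg @ self.Rg.T
        return dx


class Conv1D(Layer):
    """Valid cross-correlation over the temporal axis, multi-channel."""

    def __init__(self, n_in: int, n_filters: int, kernel_len: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_filters, self.kernel_len = n_in, n_filters, kernel_len
        fan_in = n_in * kernel_len
        self.W = glorot_uniform(rng, fan_in, n_filters,
                                (kernel_len, n_in, n_filters))
        self.b = np.zeros(n_filters)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._x = None

    def forward(self, x, training=False):
        B, L, C = x.shape
        k = self.kernel_len
        if k > L:
            raise ValueError(f"kernel length {k} exceeds input length {L}")
        self._x = x
        Lout = L - k + 1
        y = np.broadcast_to(self.b, (B, Lout, self.n_filters)).copy()
        for j in range(k):
            y += x[:, j:j + Lout, :] @ self.W[j]
        return y

    def backward(self, grad_out):
        x = self._x
        B, L, C = x.shape
        k = self.kernel_len
        Lout = L - k + 1
        dx = np.zeros_like(x)
        gW, gb = self.grads
        gb += grad_out.sum(axis=(0, 1))
        for j in range(k):
            gW[j] += np.einsum("blc,blf->cf", x[:, j:j + Lout, :], grad_out)
            dx[:, j:j + Lout, :] += grad_out @ self.W[j].T
        return dx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over the (batch, length) axes."""

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.n_channels = n_channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._cache = None

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = (self.momentum * self.running_mean
                                      + (1 - self.momentum) * mu)
            self.running_var[...] = (self.momentum * self.running_var
                                     + (1 - self.momentum) * var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std, axes, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, grad_out):
        xhat, inv_std, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.grads[0] += (grad_out * xhat).sum(axis=axes)
        self.grads[1] += grad_out.sum(axis=axes)
        g = grad_out * self.gamma
        return inv_std * (g - g.mean(axis=axes)
                          - xhat * (g * xhat).mean(axis=axes))


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the temporal axis; remainder dropped."""

    def __init__(self, size: int):
        super().__init__()
        if size < 1:
            raise ValueError("pool size must be >= 1")
        self.size = size
        self._cache = None

    def forward(self, x, training=False):
        B, L, C = x.shape
        n_win = L // self.size
        win = x[:, : n_win * self.size, :].reshape(B, n_win, self.size, C)
        idx = win.argmax(axis=2)
        self._cache = (idx, x.shape, n_win)
        return np.take_along_axis(win, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, grad_out):
        idx, (B, L, C), n_win = self._cache
        dwin = np.zeros((B, n_win, self.size, C))
        np.put_along_axis(dwin, idx[:, :, None, :], grad_out[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C))
        dx[:, : n_win * self.size, :] = dwin.reshape(B, n_win * self.size, C)
        return dx


class GlobalAvgPool1D(Layer):
    """Average over the whole temporal axis, per channel."""

    def __init__(self):
        super().__init__()
        self._shape = None

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, grad_out):
        B, L, C = self._shape
        return np.broadcast_to(grad_out[:, None, :] / L, (B, L, C)).copy()


class SoftmaxCrossEntropy:
    """Softmax output combined with mean cross-entropy loss.

    ``forward`` returns class probabilities; ``loss_and_grad`` additionally
    returns the loss and the gradient with respect to the logits, with
    optional per-example weights (used for class weighting).
    """

    @staticmethod
    def probabilities(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    @classmethod
    def loss_and_grad(cls, logits: np.ndarray, y: np.ndarray,
                      sample_weight: np.ndarray | None = None
                      ) -> tuple[float, np.ndarray]:
        p = cls.probabilities(logits)
        flat_p = p.reshape(-1, p.shape[-1])
        flat_y = y.reshape(-1)
        n = flat_y.shape[0]
        w = np.ones(n) if sample_weight is None else sample_weight.reshape(-1)
        wsum = w.sum()
        eps = 1e-12
        loss = -(w * np.log(flat_p[np.arange(n), flat_y] + eps)).sum() / wsum
        grad = flat_p.copy()
        grad[np.arange(n), flat_y] -= 1.0
        grad *= (w / wsum)[:, None]
        return float(loss), grad.reshape(logits.shape)


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class SGD:
    """Plain stochastic gradient descent with optional momentum."""

    def __init__(self, lr: float = 1e-2, momentum: float = 0.0):
        self.lr, self.momentum = lr, momentum
        self._v: list[np.ndarray] | None = None

    def step(self, params, grads):
        if self._v is None:
            self._v = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._v):
            v *= self.momentum
            v -= self.lr * g
            p += v


OPTIMIZERS = {"adam": Adam, "sgd": SGD}
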