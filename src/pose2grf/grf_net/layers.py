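"""Numpy building blocks: LSTM forward/backward, bidirectional stacking,
inverted dropout, a per-timestep affine head, MSE loss and Adam.

Everything operates on ``(batch, time, features)`` float64 arrays. Gradients
are exact analytic backpropagation-through-time; ``tests`` verify them
against central finite differences.
"""

from __future__ import annotations

import numpy as np

from pose2grf.grf_net import _kernels


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def init_lstm_params(rng: np.random.Generator, n_in: int, n_hidden: int) -> dict[str, np.ndarray]:
    """Glorot-uniform input/recurrent kernels; forget-gate bias starts at 1."""
    lim_w = np.sqrt(6.0 / (n_in + 4 * n_hidden))
    lim_u = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
    b = np.zeros(4 * n_hidden)
    b[n_hidden : 2 * n_hidden] = 1.0
    return {
        "W": rng.uniform(-lim_w, lim_w, size=(n_in, 4 * n_hidden)),
        "U": rng.uniform(-lim_u, lim_u, size=(n_hidden, 4 * n_hidden)),
        "b": b,
    }


def init_dense_params(rng: np.random.Generator, n_in: int, n_out: int) -> dict[str, np.ndarray]:
    lim = np.sqrt(6.0 / (n_in + n_out))
    return {"W": rng.uniform(-lim, lim, size=(n_in, n_out)), "b": np.zeros(n_out)}


def lstm_forward(X: np.ndarray, params: dict, reverse: bool = False):
    """Run an LSTM over time. ``X`` is (B, T, I); returns hidden states
    (B, T, H) in original time order plus the cache for backprop.

    The input-kernel product is hoisted out of the time loop (one big matmul
    over all timesteps); only the recurrent product stays sequential.
    """
    W, U, b = params["W"], params["U"], params["b"]
    B, T, _ = X.shape
    H = U.shape[0]
    XW = X @ W + b  # (B, T, 4H)
    if _kernels.HAVE_NUMBA:
        Hs, I_, F_, G_, O_, Cprev, TC = _kernels.lstm_seq_forward(
            np.ascontiguousarray(XW), np.ascontiguousarray(U), reverse
        )
        cache = {"X": X, "Hs": Hs, "gates": (I_, F_, G_, O_, Cprev, TC),
                 "reverse": reverse, "H": H}
        return Hs, cache
    order = range(T - 1, -1, -1) if reverse else range(T)
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    Hs = np.zeros((B, T, H))
    I_ = np.empty((B, T, H))
    F_ = np.empty((B, T, H))
    G_ = np.empty((B, T, H))
    O_ = np.empty((B, T, H))
    Cprev = np.empty((B, T, H))
    TC = np.empty((B, T, H))
    for t in order:
        z = XW[:, t, :] + h @ U
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        Cprev[:, t, :] = c
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        Hs[:, t, :] = h
        I_[:, t, :], F_[:, t, :], G_[:, t, :], O_[:, t, :], TC[:, t, :] = i, f, g, o, tc
    cache = {"X": X, "Hs": Hs, "gates": (I_, F_, G_, O_, Cprev, TC), "reverse": reverse, "H": H}
    return Hs, cache


def lstm_backward(dHs: np.ndarray, cache: dict, params: dict):
    """Backprop through time. ``dHs`` matches the forward output; returns
    (dX, grads) with grads keyed like ``params``.

    Per-step work is elementwise plus the recurrent product; the kernel
    gradients and input gradients are single matmuls over the stacked
    pre-activation gradients.
    """
    W, U = params["W"], params["U"]
    X = cache["X"]
    H = cache["H"]
    Hs = cache["Hs"]
    I_, F_, G_, O_, Cprev, TC = cache["gates"]
    B, T, _ = X.shape
    reverse = cache["reverse"]
    # hidden state fed into step t: the state produced by the previous step
    # in iteration order (zero at the sequence edge)
    Hprev = np.zeros_like(Hs)
    if reverse:
        Hprev[:, :-1, :] = Hs[:, 1:, :]
    else:
        Hprev[:, 1:, :] = Hs[:, :-1, :]
    if _kernels.HAVE_NUMBA:
        I_, F_, G_, O_, Cprev, TC = cache["gates"]
        dZ = _kernels.lstm_seq_backward(
            np.ascontiguousarray(dHs), I_, F_, G_, O_, Cprev, TC,
            np.ascontiguousarray(U.T), reverse,
        )
        flat_dZ = dZ.reshape(B * T, 4 * H)
        grads = {
            "W": X.reshape(B * T, -1).T @ flat_dZ,
            "U": Hprev.reshape(B * T, H).T @ flat_dZ,
            "b": flat_dZ.sum(axis=0),
        }
        return dZ @ W.T, grads
    order = range(T) if reverse else range(T - 1, -1, -1)
    dZ = np.empty((B, T, 4 * H))
    I_, F_, G_, O_, Cprev, TC = cache["gates"]
    dh_next = np.zeros((B, H))
    dc_next = np.zeros((B, H))
    for t in order:
        i, f, g, o, c_prev, tc = (
            I_[:, t, :], F_[:, t, :], G_[:, t, :], O_[:, t, :], Cprev[:, t, :], TC[:, t, :]
        )
        dh = dHs[:, t, :] + dh_next
        do = dh * tc
        dc = dc_next + dh * o * (1.0 - tc**2)
        dc_next = dc * f
        dz = dZ[:, t, :]
        dz[:, :H] = dc * g * i * (1.0 - i)
        dz[:, H : 2 * H] = dc * c_prev * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g**2)
        dz[:, 3 * H :] = do * o * (1.0 - o)
        dh_next = dz @ U.T
    flat_dZ = dZ.reshape(B * T, 4 * H)
    grads = {
        "W": X.reshape(B * T, -1).T @ flat_dZ,
        "U": Hprev.reshape(B * T, H).T @ flat_dZ,
        "b": flat_dZ.sum(axis=0),
    }
    dX = dZ @ W.T
    return dX, grads


class BiLSTMRegressor:
    """Stacked bidirectional LSTM with a per-timestep affine head.

    ``n_layers`` bi-LSTM layers of ``n_hidden`` units per direction, inverted
    dropout between layers (and before the head) during training, and a dense
    map from the 2*n_hidden concatenated states to ``n_out`` outputs at every
    timestep.
    """

    def __init__(
        self,
        n_in: int,
        n_hidden: int,
        n_out: int,
        n_layers: int = 2,
        dropout: float = 0.5,
        seed: int = 0,
        dtype=np.float64,
    ):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if min(n_in, n_hidden, n_out, n_layers) < 1:
            raise ValueError("all sizes must be positive")
        self.n_in, self.n_hidden, self.n_out = n_in, n_hidden, n_out
        self.n_layers = n_layers
        self.dropout = dropout
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        d_in = n_in
        for layer in range(n_layers):
            for direction in ("f", "r"):
                for k, v in init_lstm_params(rng, d_in, n_hidden).items():
                    self.params[f"l{layer}{direction}_{k}"] = v.astype(self.dtype)
            d_in = 2 * n_hidden
        for k, v in init_dense_params(rng, 2 * n_hidden, n_out).items():
            self.params[f"head_{k}"] = v.astype(self.dtype)

    def _layer_params(self, layer: int, direction: str) -> dict[str, np.ndarray]:
        return {k: self.params[f"l{layer}{direction}_{k}"] for k in ("W", "U", "b")}

    def forward(self, X: np.ndarray, training: bool = False, rng: np.random.Generator | None = None):
        """Returns (Y, cache); Y is (B, T, n_out). Dropout is active only
        when ``training`` and a rng is supplied."""
        X = np.asarray(X, dtype=self.dtype)
        cache: dict = {"layers": [], "masks": []}
        A = X
        for layer in range(self.n_layers):
            Hf, cf = lstm_forward(A, self._layer_params(layer, "f"), reverse=False)
            Hr, cr = lstm_forward(A, self._layer_params(layer, "r"), reverse=True)
            A = np.concatenate([Hf, Hr], axis=2)
            mask = None
            if training and self.dropout > 0.0:
                if rng is None:
                    raise ValueError("training-mode forward needs an rng for dropout")
                u = rng.random(A.shape, dtype=np.float32)
                mask = ((u >= self.dropout) / (1.0 - self.dropout)).astype(self.dtype)
                A = A * mask
            cache["layers"].append((cf, cr))
            cache["masks"].append(mask)
        cache["head_in"] = A
        Y = A @ self.params["head_W"] + self.params["head_b"]
        return Y, cache

    def backward(self, dY: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        A = cache["head_in"]
        B, T, D = A.shape
        grads["head_W"] = A.reshape(B * T, D).T @ dY.reshape(B * T, -1)
        grads["head_b"] = dY.sum(axis=(0, 1))
        dA = dY @ self.params["head_W"].T
        for layer in range(self.n_layers - 1, -1, -1):
            mask = cache["masks"][layer]
            if mask is not None:
                dA = dA * mask
            H = self.n_hidden
            cf, cr = cache["layers"][layer]
            dXf, gf = lstm_backward(dA[:, :, :H], cf, self._layer_params(layer, "f"))
            dXr, gr = lstm_backward(dA[:, :, H:], cr, self._layer_params(layer, "r"))
            for k in ("W", "U", "b"):
                grads[f"l{layer}f_{k}"] = gf[k]
                grads[f"l{layer}r_{k}"] = gr[k]
            dA = dXf + dXr
        return grads

    def predict(self, X: np.ndarray) -> np.ndarray:
        Y, _ = self.forward(X, training=False)
        return Y

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
        self.dtype = self.params["head_W"].dtype


def mse_loss(Y: np.ndarray, T: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all samples, frames and components, with its
    gradient w.r.t. ``Y``."""
    diff = Y - T
    loss = float(np.mean(diff**2))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.003,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g**2
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
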