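"""Look-back-window LSTM residual forecaster, implemented in numpy.

The network predicts the next residual vector from the last ``p`` scaled
residual observations. Cells follow the standard gate recurrence

    i_k = sigma(W_i [h_{k-1}, x_k] + b_i)        input gate
    f_k = sigma(W_f [h_{k-1}, x_k] + b_f)        forget gate
    chat_k = phi(W_c [h_{k-1}, x_k] + b_c)       candidate cell
    c_k = f_k . c_{k-1} + i_k . chat_k           cell update
    o_k = sigma(W_o [h_{k-1}, x_k] + b_o)        output gate
    h_k = o_k . phi(c_k)                         hidden state

with h_0 = c_0 = 0 and phi = tanh by default (configurable); the final
hidden state of the last layer feeds a linear dense layer of size m.
Training minimizes one-step MSE by backpropagation through time with a
chronological 80/20 train/validation split and early stopping.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

UNIT_CHOICES = (32, 64, 128, 256)
ACTIVATION_CHOICES = ("relu", "elu", "tanh", "sigmoid", "leaky_relu")
BATCH_CHOICES = (16, 32, 64, 128)
OPTIMIZER_CHOICES = ("adam", "rmsprop", "nadam")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _get_activation(name: str, alpha: float) -> tuple[Callable, Callable]:
    """(phi, phi'(x) given x and phi(x))."""
    if name == "tanh":
        return np.tanh, lambda x, y: 1.0 - y * y
    if name == "sigmoid":
        return _sigmoid, lambda x, y: y * (1.0 - y)
    if name == "relu":
        return (lambda x: np.maximum(x, 0.0),
                lambda x, y: (x > 0).astype(float))
    if name == "elu":
        def elu(x):
            return np.where(x > 0, x, np.expm1(np.clip(x, -60, 60)))
        return elu, lambda x, y: np.where(x > 0, 1.0, y + 1.0)
    if name == "leaky_relu":
        return (lambda x: np.where(x > 0, x, alpha * x),
                lambda x, y: np.where(x > 0, 1.0, alpha))
    raise ValueError(f"unknown activation {name!r}")


@dataclass(frozen=True)
class LSTMConfig:
    """Hyper-parameters; domains mirror the tuning search space."""

    units: tuple[int, int] = (64, 64)
    activation: str = "tanh"
    leaky_alpha: float = 0.01
    dropout: float = 0.0
    recurrent_dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    optimizer: str = "adam"
    output_dim: int = 6

    def __post_init__(self) -> None:
        if any(u not in UNIT_CHOICES for u in self.units) or len(self.units) != 2:
            raise ValueError(f"units must be two of {UNIT_CHOICES}")
        if self.activation not in ACTIVATION_CHOICES:
            raise ValueError(f"activation must be one of {ACTIVATION_CHOICES}")
        if not 0.01 <= self.leaky_alpha <= 0.3:
            raise ValueError("leaky_alpha must lie in [0.01, 0.3]")
        for d in (self.dropout, self.recurrent_dropout):
            if not 0.0 <= d <= 0.5:
                raise ValueError("dropout rates must lie in [0, 0.5]")
        if not 1e-5 <= self.learning_rate <= 1e-2:
            raise ValueError("learning_rate must lie in [1e-5, 1e-2]")
        if self.batch_size not in BATCH_CHOICES:
            raise ValueError(f"batch_size must be one of {BATCH_CHOICES}")
        if self.optimizer not in OPTIMIZER_CHOICES:
            raise ValueError(f"optimizer must be one of {OPTIMIZER_CHOICES}")


class _Optimizer:
    """Adam / Nadam / RMSprop on a flat list of parameter arrays."""

    def __init__(self, kind: str, lr: float):
        self.kind = kind
        self.lr = lr
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        b1, b2, eps = 0.9, 0.999, 1e-7
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            if self.kind == "rmsprop":
                v *= 0.9
                v += 0.1 * g * g
                p -= self.lr * g / (np.sqrt(v) + eps)
                continue
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            if self.kind == "nadam":
                mhat = b1 * mhat + (1 - b1) * g / (1 - b1**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


class LSTMNetwork:
    """Two stacked LSTM layers plus a linear output head."""

    def __init__(self, cfg: LSTMConfig, input_dim: int,
                 rng: np.random.Generator | int = 0):
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        self.cfg = cfg
        self.input_dim = input_dim
        self.phi, self.dphi = _get_activation(cfg.activation, cfg.leaky_alpha)
        self.layers = []
        d = input_dim
        for H in cfg.units:
            lim_x = np.sqrt(6.0 / (d + 4 * H))
            lim_h = np.sqrt(6.0 / (H + 4 * H))
            Wx = rng.uniform(-lim_x, lim_x, size=(4 * H, d))
            Wh = rng.uniform(-lim_h, lim_h, size=(4 * H, H))
            b = np.zeros(4 * H)
            b[H:2 * H] = 1.0  # forget-gate bias init
            self.layers.append({"Wx": Wx, "Wh": Wh, "b": b, "H": H})
            d = H
        lim = np.sqrt(6.0 / (d + cfg.output_dim))
        self.Wy = rng.uniform(-lim, lim, size=(cfg.output_dim, d))
        self.by = np.zeros(cfg.output_dim)

    @classmethod
    def from_dimensions(cls, units: tuple[int, ...], input_dim: int,
                        output_dim: int, activation: str = "tanh",
                        leaky_alpha: float = 0.01,
                        rng: np.random.Generator | int = 0) -> "LSTMNetwork":
        """Build a network of arbitrary layer sizes (bypasses the tuning-space
        domain checks; used for small reference cells and tests)."""
        rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        net = object.__new__(cls)
        net.cfg = LSTMConfig()  # defaults; dropout off
        net.input_dim = input_dim
        net.phi, net.dphi = _get_activation(activation, leaky_alpha)
        net.layers = []
        d = input_dim
        for H in units:
            lim_x = np.sqrt(6.0 / (d + 4 * H))
            lim_h = np.sqrt(6.0 / (H + 4 * H))
            net.layers.append({
                "Wx": rng.uniform(-lim_x, lim_x, size=(4 * H, d)),
                "Wh": rng.uniform(-lim_h, lim_h, size=(4 * H, H)),
                "b": np.zeros(4 * H), "H": H,
            })
            d = H
        lim = np.sqrt(6.0 / (d + output_dim))
        net.Wy = rng.uniform(-lim, lim, size=(output_dim, d))
        net.by = np.zeros(output_dim)
        return net

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.layers:
            out += [layer["Wx"], layer["Wh"], layer["b"]]
        out += [self.Wy, self.by]
        return out

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.parameters(), weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[...] = w

    # -- forward ------------------------------------------------------------
    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Predictions for a batch of windows, shape (B, p, input_dim).

        In training mode applies inverted dropout on layer inputs and
        recurrent dropout on the hidden state, with masks fixed across the
        window's timesteps; at inference dropout is off, so the forward pass
        is deterministic.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            X = X[None]
        B, p, d = X.shape
        if d != self.input_dim:
            raise ValueError(
                f"window has {d} channels, network expects {self.input_dim}")
        caches = []
        inp = X
        for layer in self.layers:
            H = layer["H"]
            Wx, Wh, b = layer["Wx"], layer["Wh"], layer["b"]
            drop_in = drop_h = None
            if train and rng is not None:
                if self.cfg.dropout > 0:
                    drop_in = (rng.random((B, inp.shape[2])) >= self.cfg.dropout
                               ) / (1 - self.cfg.dropout)
                if self.cfg.recurrent_dropout > 0:
                    drop_h = (rng.random((B, H)) >= self.cfg.recurrent_dropout
                              ) / (1 - self.cfg.recurrent_dropout)
            h = np.zeros((B, H))
            c = np.zeros((B, H))
            steps = []
            hs = np.empty((B, p, H))
            for k in range(p):
                xk = inp[:, k] if drop_in is None else inp[:, k] * drop_in
                h_in = h if drop_h is None else h * drop_h
                z = xk @ Wx.T + h_in @ Wh.T + b
                zi, zf, zc, zo = np.split(z, 4, axis=1)
                i = _sigmoid(zi)
                f = _sigmoid(zf)
                g = self.phi(zc)
                o = _sigmoid(zo)
                c_new = f * c + i * g
                tc = self.phi(c_new)
                h_new = o * tc
                steps.append({"xk": xk, "h_prev": h_in, "c_prev": c,
                              "i": i, "f": f, "g": g, "o": o,
                              "zc": zc, "c": c_new, "tc": tc})
                h, c = h_new, c_new
                hs[:, k] = h
            caches.append({"steps": steps, "drop_in": drop_in, "drop_h": drop_h,
                           "inp": inp, "hs": hs})
            inp = hs
        y = h @ self.Wy.T + self.by
        return y, caches

    def predict(self, X: np.ndarray) -> np.ndarray:
        y, _ = self.forward(X, train=False)
        return y

    # -- backward -----------------------------------------------------------
    def backward(self, caches, dy: np.ndarray) -> list[np.ndarray]:
        """Gradients of the loss w.r.t. parameters() given dL/dy."""
        B, p = caches[0]["inp"].shape[:2]
        h_last = caches[-1]["hs"][:, -1]
        dWy = dy.T @ h_last
        dby = dy.sum(axis=0)
        # incoming dh per timestep for the top layer: only the last step
        dh_seq = np.zeros_like(caches[-1]["hs"])
        dh_seq[:, -1] = dy @ self.Wy
        grads_layers = []
        for li in range(len(self.layers) - 1, -1, -1):
            layer = self.layers[li]
            cache = caches[li]
            Wx, Wh = layer["Wx"], layer["Wh"]
            H = layer["H"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros(4 * H)
            dh_next = np.zeros((B, H))
            dc_next = np.zeros((B, H))
            dx_seq = np.zeros_like(cache["inp"])
            for k in range(p - 1, -1, -1):
                st = cache["steps"][k]
                dh = dh_seq[:, k] + dh_next
                do = dh * st["tc"]
                dc = dc_next + dh * st["o"] * self.dphi(st["c"], st["tc"])
                di = dc * st["g"]
                df = dc * st["c_prev"]
                dg = dc * st["i"]
                dc_next = dc * st["f"]
                dzi = di * st["i"] * (1 - st["i"])
                dzf = df * st["f"] * (1 - st["f"])
                dzc = dg * self.dphi(st["zc"], st["g"])
                dzo = do * st["o"] * (1 - st["o"])
                dz = np.concatenate([dzi, dzf, dzc, dzo], axis=1)
                dWx += dz.T @ st["xk"]
                dWh += dz.T @ st["h_prev"]
                db += dz.sum(axis=0)
                dxk = dz @ Wx
                if cache["drop_in"] is not None:
                    dxk = dxk * cache["drop_in"]
                dx_seq[:, k] = dxk
                dh_next = dz @ Wh
                if cache["drop_h"] is not None:
                    dh_next = dh_next * cache["drop_h"]
            grads_layers.insert(0, (dWx, dWh, db))
            dh_seq = dx_seq  # feeds the layer below at every timestep
        grads: list[np.ndarray] = []
        for g3 in grads_layers:
            grads += list(g3)
        grads += [dWy, dby]
        return grads


def lstm_forward(network: LSTMNetwork, window: np.ndarray) -> np.ndarray:
    """One-window prediction through the gate recurrence (inference mode)."""
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("window must be a p x m matrix")
    return network.predict(window[None])[0]


@dataclass
class TrainingLog:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def train_lstm(
    inputs: np.ndarray,
    targets: np.ndarray,
    cfg: LSTMConfig,
    split: float = 0.8,
    patience: int = 15,
    max_epochs: int = 500,
    rng_seed: int = 0,
) -> tuple[LSTMNetwork, float, TrainingLog]:
    """Fit the network on windowed residuals; returns (model, MSE_val, log).

    The window set is split chronologically into a fitting subset and an
    internal validation subset (default 80/20). Training stops once the
    validation MSE has not improved for ``patience`` epochs and the best
    weights are restored. Reproducible given ``rng_seed``.
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    n = len(inputs)
    n_train = int(round(split * n))
    n_train = min(max(n_train, 1), n - 1) if n >= 2 else n_train
    if n < 2 or n - n_train < 1:
        raise ValueError("need at least one training and one validation pair")
    X_tr, y_tr = inputs[:n_train], targets[:n_train]
    X_val, y_val = inputs[n_train:], targets[n_train:]

    rng = np.random.default_rng(rng_seed)
    cfg = LSTMConfig(**{**cfg.__dict__, "output_dim": targets.shape[1]})
    net = LSTMNetwork(cfg, input_dim=inputs.shape[2], rng=rng)
    opt = _Optimizer(cfg.optimizer, cfg.learning_rate)

    def mse(model, X, y):
        pred = model.predict(X)
        return float(np.mean((pred - y) ** 2))

    log = TrainingLog()
    best_val = np.inf
    best_weights = net.get_weights()
    wait = 0
    for epoch in range(max_epochs):
        order = rng.permutation(n_train)
        ep_loss = 0.0
        for start in range(0, n_train, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, yb = X_tr[idx], y_tr[idx]
            pred, caches = net.forward(Xb, train=True, rng=rng)
            err = pred - yb
            ep_loss += float(np.sum(err ** 2))
            dy = 2.0 * err / err.size
            grads = net.backward(caches, dy)
            opt.step(net.parameters(), grads)
        log.train_loss.append(ep_loss / (n_train * targets.shape[1]))
        val = mse(net, X_val, y_val)
        log.val_loss.append(val)
        if val < best_val - 1e-12:
            best_val = val
            best_weights = net.get_weights()
            log.best_epoch = epoch
            wait = 0
        else:
            wait += 1
            if wait >= patience:
                log.stopped_epoch = epoch
                break
    net.set_weights(best_weights)
    return net, best_val, log
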