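"""Stacked-LSTM sequence classifier for 60-s multimodal segments.

The network is the forecasting architecture used throughout this package:
4 LSTM layers of 128 hidden units, a dropout layer (rate 0.2) after each LSTM
layer, and a fully connected head with sigmoid activation producing one
preictal probability per segment from the last timestep's hidden state.

It is implemented directly in NumPy — forward pass, truncated-free BPTT and
Adam — with float32 arithmetic so that training and inference run on a single
CPU.  Long segments are decimated by ``temporal_stride`` before entering the
recurrence (7680 samples → 7680/stride timesteps); full resolution is
stride 1.  Initialization, dropout and batch shuffling are all driven by an
explicit seed, so two builds (or two training runs) with the same seed are
bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy.special import expit as _sigmoid

__all__ = ["ModelConfig", "TrainConfig", "LSTMForecaster", "build_model", "train", "predict"]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture constants: 4 LSTM layers × 128 hidden, dropout 0.2."""

    n_channels: int = 17
    n_lstm_layers: int = 4
    hidden_size: int = 128
    dropout: float = 0.2
    temporal_stride: int = 16  # 7680-step segments → 480 steps by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.n_lstm_layers < 1 or self.hidden_size < 1:
            raise ValueError("invalid architecture dimensions")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.temporal_stride < 1:
            raise ValueError("temporal_stride must be >= 1")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (binary cross-entropy + Adam by default)."""

    loss: str = "bce"
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    epochs: int = 8
    batch_size: int = 256
    seed: int = 0
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.loss != "bce" or self.optimizer != "adam":
            raise ValueError("supported: loss='bce', optimizer='adam'")


class LSTMForecaster:
    """Stacked LSTM with per-layer dropout and a sigmoid linear head.

    Parameters are stored as one weight matrix per layer with gate order
    (input, forget, cell, output): ``W[l]`` has shape
    (input_size_l + hidden, 4·hidden) and acts on ``[x_t, h_{t-1}]``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        H = config.hidden_size
        rng = np.random.default_rng(config.seed)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for layer in range(config.n_lstm_layers):
            in_size = config.n_channels if layer == 0 else H
            k = 1.0 / np.sqrt(H)
            self.W.append(rng.uniform(-k, k, size=(in_size + H, 4 * H)).astype(np.float32))
            b = rng.uniform(-k, k, size=4 * H).astype(np.float32)
            b[H:2 * H] += 1.0  # forget-gate bias init helps gradient flow
            self.b.append(b)
        k = 1.0 / np.sqrt(H)
        self.w_head = rng.uniform(-k, k, size=H).astype(np.float32)
        self.b_head = np.float32(rng.uniform(-k, k))

    # -- parameter plumbing -------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [*self.W, *self.b, self.w_head, np.atleast_1d(self.b_head)]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = self.config.n_lstm_layers
        self.W = [p.astype(np.float32) for p in params[:n]]
        self.b = [p.astype(np.float32) for p in params[n:2 * n]]
        self.w_head = params[2 * n].astype(np.float32)
        self.b_head = np.float32(np.asarray(params[2 * n + 1]).ravel()[0])

    # -- forward ------------------------------------------------------------
    def _prepare(self, x: np.ndarray) -> np.ndarray:
        """(n, C, T) segment tensor → decimated (T', n, C) float32 sequence."""
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 3 or x.shape[1] != self.config.n_channels:
            raise ValueError(
                f"expected (n, {self.config.n_channels}, T) input, got {x.shape}")
        x = x[:, :, ::self.config.temporal_stride]
        return np.ascontiguousarray(np.transpose(x, (2, 0, 1)))

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None):
        """Probabilities (and caches when training) for a (n, C, T) batch."""
        cfg = self.config
        H = cfg.hidden_size
        seq = self._prepare(x)
        T, B, _ = seq.shape
        if training and cfg.dropout > 0 and rng is None:
            raise ValueError("training forward pass with dropout needs an rng")
        caches = []
        layer_in = seq
        for layer in range(cfg.n_lstm_layers):
            W, b = self.W[layer], self.b[layer]
            h = np.zeros((B, H), dtype=np.float32)
            c = np.zeros((B, H), dtype=np.float32)
            gates_i = np.empty((T, B, H), np.float32)
            gates_f = np.empty((T, B, H), np.float32)
            gates_g = np.empty((T, B, H), np.float32)
            gates_o = np.empty((T, B, H), np.float32)
            cs = np.empty((T, B, H), np.float32)
            hs = np.empty((T, B, H), np.float32)
            for t in range(T):
                z = np.concatenate([layer_in[t], h], axis=1) @ W + b
                i = _sigmoid(z[:, :H])
                f = _sigmoid(z[:, H:2 * H])
                g = np.tanh(z[:, 2 * H:3 * H])
                o = _sigmoid(z[:, 3 * H:])
                c = f * c + i * g
                h = o * np.tanh(c)
                gates_i[t], gates_f[t], gates_g[t], gates_o[t] = i, f, g, o
                cs[t], hs[t] = c, h
            if training and cfg.dropout > 0:
                mask = (rng.random((T, B, H), dtype=np.float32) >= cfg.dropout) \
                    .astype(np.float32) / np.float32(1 - cfg.dropout)
                out = hs * mask
            else:
                mask = None
                out = hs
            caches.append((layer_in, gates_i, gates_f, gates_g, gates_o, cs, hs, mask))
            layer_in = out
        logits = layer_in[-1] @ self.w_head + self.b_head
        probs = _sigmoid(logits)
        if training:
            return probs, (caches, layer_in[-1])
        return probs

    # -- backward -----------------------------------------------------------
    def backward(self, probs: np.ndarray, y: np.ndarray, cache) -> list[np.ndarray]:
        """Gradients of mean BCE loss, in the order of :meth:`parameters`."""
        cfg = self.config
        H = cfg.hidden_size
        caches, head_in = cache
        B = probs.size
        dlogit = ((probs - y) / B).astype(np.float32)
        dw_head = head_in.T @ dlogit
        db_head = dlogit.sum()
        dW_list: list[np.ndarray] = [None] * cfg.n_lstm_layers  # type: ignore
        db_list: list[np.ndarray] = [None] * cfg.n_lstm_layers  # type: ignore

        d_out = None  # gradient wrt the layer's post-dropout output, (T,B,H)
        for layer in reversed(range(cfg.n_lstm_layers)):
            layer_in, gi, gf, gg, go, cs, hs, mask = caches[layer]
            T, _, _ = gi.shape
            if layer == cfg.n_lstm_layers - 1:
                d_out = np.zeros_like(hs)
                d_out[-1] = np.outer(dlogit, self.w_head)
            if mask is not None:
                d_h_seq = d_out * mask
            else:
                d_h_seq = d_out
            W = self.W[layer]
            W_h = W[-H:]  # rows acting on h_{t-1}
            dZ = np.empty((T, hs.shape[1], 4 * H), dtype=np.float32)
            dh_next = np.zeros_like(hs[0])
            dc_next = np.zeros_like(hs[0])
            for t in range(T - 1, -1, -1):
                dh = d_h_seq[t] + dh_next
                i, f, g, o = gi[t], gf[t], gg[t], go[t]
                tc = np.tanh(cs[t])
                do = dh * tc
                dc = dh * o * (1 - tc * tc) + dc_next
                di = dc * g
                dg = dc * i
                c_prev = cs[t - 1] if t > 0 else np.zeros_like(cs[0])
                df = dc * c_prev
                dc_next = dc * f
                dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                     dg * (1 - g * g), do * o * (1 - o)], axis=1)
                dZ[t] = dz
                dh_next = dz @ W_h.T
            in_size = layer_in.shape[2]
            h_prev = np.concatenate([np.zeros_like(hs[:1]), hs[:-1]], axis=0)
            X_cat = np.concatenate([layer_in, h_prev], axis=2)
            TB = T * hs.shape[1]
            dW_list[layer] = X_cat.reshape(TB, in_size + H).T @ dZ.reshape(TB, 4 * H)
            db_list[layer] = dZ.sum(axis=(0, 1))
            d_out = (dZ.reshape(TB, 4 * H) @ W[:in_size].T).reshape(T, -1, in_size)
        return [*dW_list, *db_list, dw_head, np.atleast_1d(np.float32(db_head))]


def build_model(config: ModelConfig = ModelConfig()) -> LSTMForecaster:
    """Construct the classifier with seed-reproducible initialization."""
    return LSTMForecaster(config)


def _bce(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs, 1e-7, 1 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def train(model: LSTMForecaster, x: np.ndarray, y: np.ndarray,
          config: TrainConfig = TrainConfig()) -> list[float]:
    """Train in place with Adam on mean binary cross-entropy.

    ``x`` is (n, C, T) and ``y`` binary {0,1}.  Returns the per-epoch mean
    training loss.  Aborts with diagnostics if the loss turns non-finite.
    """
    y = np.asarray(y, dtype=np.float32).ravel()
    n = len(y)
    if n == 0 or n != len(x):
        raise ValueError("x and y must be non-empty and aligned")
    rng = np.random.default_rng(config.seed)
    params = model.parameters()
    m = [np.zeros_like(p, dtype=np.float64) for p in params]
    v = [np.zeros_like(p, dtype=np.float64) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    history: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            probs, cache = model.forward(x[idx], training=True, rng=rng)
            loss = _bce(probs, y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch_size}: "
                    f"loss={loss}; consider lowering the learning rate")
            losses.append(loss)
            grads = model.backward(probs, y[idx], cache)
            gnorm = np.sqrt(sum(float(np.sum(g.astype(np.float64) ** 2)) for g in grads))
            scale = min(1.0, config.clip_norm / (gnorm + 1e-12))
            step += 1
            params = model.parameters()
            new_params = []
            for p, g, mi, vi in zip(params, grads, m, v):
                g = g.astype(np.float64) * scale
                mi[...] = beta1 * mi + (1 - beta1) * g
                vi[...] = beta2 * vi + (1 - beta2) * g * g
                mhat = mi / (1 - beta1 ** step)
                vhat = vi / (1 - beta2 ** step)
                new_params.append((p.astype(np.float64)
                                   - config.learning_rate * mhat / (np.sqrt(vhat) + eps))
                                  .astype(np.float32))
            model.set_parameters(new_params)
        history.append(float(np.mean(losses)))
    return history


def predict(model: LSTMForecaster, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
    """Deterministic (dropout-free) per-segment probabilities, in input order."""
    out = []
    for lo in range(0, len(x), batch_size):
        out.append(model.forward(x[lo:lo + batch_size], training=False))
    return np.concatenate(out) if out else np.empty(0)


# -- checkpointing ----------------------------------------------------------

def save_checkpoint(model: LSTMForecaster, path) -> None:
    """Portable checkpoint: all parameters plus the embedded config."""
    arrays = {f"param_{i}": p for i, p in enumerate(model.parameters())}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path) -> LSTMForecaster:
    with np.load(path, allow_pickle=False) as data:
        cfg = ModelConfig(**json.loads(str(data["config"])))
        model = LSTMForecaster(cfg)
        n_params = len(model.parameters())
        model.set_parameters([data[f"param_{i}"] for i in range(n_params)])
    return model
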