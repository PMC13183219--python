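"""The I2I sequence classifier: stacked LSTMs feeding a fully connected funnel.

Architecture (fixed layer order)::

    input (T, D) -> LSTM(100, return sequences) -> dropout 0.30
                 -> LSTM(100, return last step) -> dropout 0.30
                 -> FC 1024 -> LeakyReLU(0.01) -> dropout 0.30
                 -> FC 256  -> LeakyReLU       -> dropout 0.30
                 -> FC 128  -> LeakyReLU       -> dropout 0.30
                 -> FC 64   -> LeakyReLU       -> dropout 0.20
                 -> FC n_classes -> softmax

Training minimises mean cross-entropy plus an L2 penalty on weight matrices,
with Adam and *global* L2-norm gradient clipping: whenever the concatenated
gradient norm exceeds the threshold the whole gradient is rescaled onto the
threshold sphere before the Adam update (the clip threshold is 0.02 in the
reference recipe; Adam's per-parameter normalisation keeps learning effective
regardless of the clip scale).

Everything is NumPy float64 and seed-deterministic: weight initialisation
(Glorot-uniform input/FC weights, per-gate orthogonal recurrent weights, zero
biases with forget-gate bias 1), epoch shuffling and dropout masks all derive
from a single ``numpy`` Generator, so two runs with identical data, config and
seed produce bit-identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "I2IModel",
    "build",
    "leaky_relu",
    "forward",
    "train",
    "predict",
    "parameter_count",
]

_GATES = 4  # input, forget, cell, output


@dataclass(frozen=True)
class NetworkConfig:
    input_dim: int
    n_classes: int
    lstm_units: int = 100
    n_lstm: int = 2
    lstm_dropout: float = 0.30
    fc_sizes: tuple[int, ...] = (1024, 256, 128, 64)
    leaky_slope: float = 0.01
    fc_dropouts: tuple[float, ...] = (0.30, 0.30, 0.30, 0.20)
    l2_coeff: float = 1e-4

    def __post_init__(self) -> None:
        if min(self.input_dim, self.n_classes, self.lstm_units, self.n_lstm) < 1:
            raise ValueError("all layer sizes must be >= 1")
        if len(self.fc_sizes) != len(self.fc_dropouts):
            raise ValueError(
                f"fc_sizes ({len(self.fc_sizes)}) and fc_dropouts "
                f"({len(self.fc_dropouts)}) must have equal length"
            )
        drops = (self.lstm_dropout, *self.fc_dropouts)
        if any(not 0.0 <= p < 1.0 for p in drops):
            raise ValueError("dropout rates must lie in [0, 1)")
        if self.leaky_slope <= 0:
            raise ValueError("leaky_slope must be > 0")


@dataclass(frozen=True)
class TrainConfig:
    """Reference recipe: Adam, lr 1e-4, 100 epochs, batch 64, clip 0.02."""

    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 64
    grad_clip: float = 0.02
    seed: int = 0
    shuffle: bool = True
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("need lr > 0, epochs >= 1, batch_size >= 1")


@dataclass
class I2IModel:
    config: NetworkConfig
    params: dict[str, np.ndarray]
    #: one row per epoch: {"epoch", "loss", "accuracy", "max_grad_norm"}
    history: list[dict] = field(default_factory=list)


def leaky_relu(x, slope: float = 0.01):
    """x for x >= 0, slope*x otherwise (elementwise on arrays)."""
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, x, slope * x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    a = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-a, a, size=(fan_in, fan_out))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def build(config: NetworkConfig, seed: int = 0) -> I2IModel:
    """Initialise an I2I model deterministically from a seed."""
    rng = np.random.default_rng(seed)
    H, p = config.lstm_units, {}
    d = config.input_dim
    for k in range(config.n_lstm):
        p[f"lstm{k}_Wx"] = _glorot(rng, d, _GATES * H)
        p[f"lstm{k}_Wh"] = np.concatenate(
            [_orthogonal(rng, H) for _ in range(_GATES)], axis=1
        )
        b = np.zeros(_GATES * H)
        b[H : 2 * H] = 1.0  # forget-gate bias
        p[f"lstm{k}_b"] = b
        d = H
    for k, width in enumerate((*config.fc_sizes, config.n_classes)):
        p[f"fc{k}_W"] = _glorot(rng, d, width)
        p[f"fc{k}_b"] = np.zeros(width)
        d = width
    return I2IModel(config=config, params=p)


def parameter_count(config: NetworkConfig) -> int:
    """Closed-form learnable-parameter count implied by the config."""
    H = config.lstm_units
    n, d = 0, config.input_dim
    for _ in range(config.n_lstm):
        n += _GATES * H * (d + H + 1)
        d = H
    for width in (*config.fc_sizes, config.n_classes):
        n += d * width + width
        d = width
    return n


# ---------------------------------------------------------------------------
# forward / backward


def _lstm_forward(x: np.ndarray, Wx, Wh, b) -> tuple[np.ndarray, dict]:
    B, T, _ = x.shape
    H = Wh.shape[0]
    xW = x @ Wx  # (B, T, 4H), hoisted out of the time loop
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = {k: np.empty((B, T, H)) for k in ("i", "f", "g", "o", "tc", "c_prev", "h_prev")}
    hs = np.empty((B, T, H))
    for t in range(T):
        z = xW[:, t] + h @ Wh + b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        cache["c_prev"][:, t] = c
        cache["h_prev"][:, t] = h
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, t] = h
        for k, v in (("i", i), ("f", f), ("g", g), ("o", o), ("tc", tc)):
            cache[k][:, t] = v
    return hs, cache


def _lstm_backward(dh_seq, x, cache, Wx, Wh):
    B, T, _ = x.shape
    H = Wh.shape[0]
    dWx = np.zeros_like(Wx)
    dWh = np.zeros_like(Wh)
    db = np.zeros(_GATES * H)
    dx = np.empty_like(x)
    dh_next = np.zeros((B, H))
    dc = np.zeros((B, H))
    dz = np.empty((B, _GATES * H))
    for t in range(T - 1, -1, -1):
        i, f, g, o, tc = (cache[k][:, t] for k in ("i", "f", "g", "o", "tc"))
        dh = dh_seq[:, t] + dh_next
        dc = dc + dh * o * (1.0 - tc * tc)
        dz[:, :H] = dc * g * i * (1.0 - i)
        dz[:, H : 2 * H] = dc * cache["c_prev"][:, t] * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = dc * i * (1.0 - g * g)
        dz[:, 3 * H :] = dh * tc * o * (1.0 - o)
        dWx += x[:, t].T @ dz
        dWh += cache["h_prev"][:, t].T @ dz
        db += dz.sum(axis=0)
        dx[:, t] = dz @ Wx.T
        dh_next = dz @ Wh.T
        dc = dc * f
    return dx, dWx, dWh, db


def _dropout_mask(rng: np.random.Generator | None, shape, rate: float) -> np.ndarray | None:
    if rng is None or rate == 0.0:
        return None
    return (rng.random(shape) >= rate) / (1.0 - rate)


def _forward_full(params, cfg: NetworkConfig, x, rng: np.random.Generator | None):
    """Forward pass; rng=None means eval mode (dropout off). Returns
    (probabilities, cache-for-backward)."""
    cache: dict = {"lstm": [], "drop": [], "fc_in": [], "pre": []}
    a = x
    for k in range(cfg.n_lstm):
        hs, lc = _lstm_forward(a, params[f"lstm{k}_Wx"], params[f"lstm{k}_Wh"],
                               params[f"lstm{k}_b"])
        cache["lstm"].append((a, lc))
        last = k == cfg.n_lstm - 1
        h = hs[:, -1] if last else hs
        m = _dropout_mask(rng, h.shape, cfg.lstm_dropout)
        cache["drop"].append(m)
        a = h if m is None else h * m
    n_fc = len(cfg.fc_sizes)
    for k in range(n_fc):
        cache["fc_in"].append(a)
        z = a @ params[f"fc{k}_W"] + params[f"fc{k}_b"]
        cache["pre"].append(z)
        a = leaky_relu(z, cfg.leaky_slope)
        m = _dropout_mask(rng, a.shape, cfg.fc_dropouts[k])
        cache["drop"].append(m)
        if m is not None:
            a = a * m
    cache["fc_in"].append(a)
    logits = a @ params[f"fc{n_fc}_W"] + params[f"fc{n_fc}_b"]
    logits = logits - logits.max(axis=1, keepdims=True)
    ex = np.exp(logits)
    probs = ex / ex.sum(axis=1, keepdims=True)
    return probs, cache


def _backward_full(params, cfg: NetworkConfig, probs, y, cache):
    B = probs.shape[0]
    grads = {}
    dz = probs.copy()
    dz[np.arange(B), y] -= 1.0
    dz /= B
    n_fc = len(cfg.fc_sizes)
    for k in range(n_fc, -1, -1):
        a_in = cache["fc_in"][k]
        grads[f"fc{k}_W"] = a_in.T @ dz
        grads[f"fc{k}_b"] = dz.sum(axis=0)
        da = dz @ params[f"fc{k}_W"].T
        if k > 0:
            m = cache["drop"][cfg.n_lstm + k - 1]
            if m is not None:
                da = da * m
            pre = cache["pre"][k - 1]
            dz = da * np.where(pre >= 0, 1.0, cfg.leaky_slope)
    dh = da  # gradient w.r.t. the (dropped-out) last LSTM output
    for k in range(cfg.n_lstm - 1, -1, -1):
        m = cache["drop"][k]
        if m is not None:
            dh = dh * m
        x_in, lc = cache["lstm"][k]
        if k == cfg.n_lstm - 1:  # return-last layer: upstream grad hits t = T-1 only
            dh_seq = np.zeros((x_in.shape[0], x_in.shape[1], cfg.lstm_units))
            dh_seq[:, -1] = dh
        else:
            dh_seq = dh
        dx, dWx, dWh, db = _lstm_backward(
            dh_seq, x_in, lc, params[f"lstm{k}_Wx"], params[f"lstm{k}_Wh"]
        )
        grads[f"lstm{k}_Wx"] = dWx
        grads[f"lstm{k}_Wh"] = dWh
        grads[f"lstm{k}_b"] = db
        dh = dx
    return grads


def _loss_and_grads(params, cfg: NetworkConfig, x, y, rng):
    probs, cache = _forward_full(params, cfg, x, rng)
    B = x.shape[0]
    ce = -np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean()
    grads = _backward_full(params, cfg, probs, y, cache)
    l2 = 0.0
    for name, w in params.items():
        if name.endswith("_W") or name.endswith("_Wx") or name.endswith("_Wh"):
            l2 += 0.5 * cfg.l2_coeff * float((w * w).sum())
            grads[name] = grads[name] + cfg.l2_coeff * w
    return ce + l2, grads, probs


def _global_norm(grads: dict[str, np.ndarray]) -> float:
    return float(np.sqrt(sum(float((g * g).sum()) for g in grads.values())))


def _clip_global(grads, threshold: float) -> float:
    """Scale all gradients onto the threshold sphere if the global L2 norm
    exceeds it; returns the post-clip norm."""
    norm = _global_norm(grads)
    if threshold is not None and norm > threshold:
        scale = threshold / norm
        for k in grads:
            grads[k] = grads[k] * scale
        return threshold
    return norm


def forward(model: I2IModel, sequence: np.ndarray, train_mode: bool = False,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Class probabilities for one (T, D) sequence or a (B, T, D) batch.

    Eval mode (default) is deterministic; train_mode samples dropout masks
    from ``rng`` (a fresh seed-0 generator if none is given).
    """
    x = np.asarray(sequence, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3 or x.shape[2] != model.config.input_dim:
        raise ValueError(
            f"expected sequences of width {model.config.input_dim}, got shape {x.shape}"
        )
    if train_mode and rng is None:
        rng = np.random.default_rng(0)
    probs, _ = _forward_full(model.params, model.config, x, rng if train_mode else None)
    return probs[0] if single else probs


def train(trainset: tuple[np.ndarray, np.ndarray], net: NetworkConfig,
          opt: TrainConfig = TrainConfig()) -> I2IModel:
    """Fit the I2I network on (sequences, labels).

    ``sequences`` is (n, T, input_dim); every class 0..n_classes-1 must be
    present. History records per-epoch mean training loss, end-of-epoch
    training accuracy, and the largest post-clip global gradient norm.
    """
    x = np.asarray(trainset[0], dtype=float)
    y = np.asarray(trainset[1], dtype=int)
    if x.ndim != 3 or x.shape[2] != net.input_dim:
        raise ValueError(f"sequences must be (n, T, {net.input_dim}), got {x.shape}")
    present = set(np.unique(y).tolist())
    missing = sorted(set(range(net.n_classes)) - present)
    if missing:
        raise ValueError(f"training labels are missing class(es) {missing}")

    rng = np.random.default_rng(opt.seed)
    model = build(net, seed=opt.seed)
    p = model.params
    m = {k: np.zeros_like(v) for k, v in p.items()}
    v = {k: np.zeros_like(w) for k, w in p.items()}
    step = 0
    n = x.shape[0]
    for epoch in range(opt.epochs):
        order = rng.permutation(n) if opt.shuffle else np.arange(n)
        losses, max_norm = [], 0.0
        for start in range(0, n, opt.batch_size):
            idx = order[start : start + opt.batch_size]
            loss, grads, _ = _loss_and_grads(p, net, x[idx], y[idx], rng)
            post_norm = _clip_global(grads, opt.grad_clip)
            max_norm = max(max_norm, post_norm)
            step += 1
            b1c = 1.0 - opt.beta1**step
            b2c = 1.0 - opt.beta2**step
            for k in p:
                m[k] = opt.beta1 * m[k] + (1 - opt.beta1) * grads[k]
                v[k] = opt.beta2 * v[k] + (1 - opt.beta2) * grads[k] ** 2
                p[k] -= opt.lr * (m[k] / b1c) / (np.sqrt(v[k] / b2c) + opt.eps)
            losses.append(loss)
        acc = float((predict(model, x) == y).mean())
        model.history.append({
            "epoch": epoch, "loss": float(np.mean(losses)),
            "accuracy": acc, "max_grad_norm": max_norm,
        })
    return model


def predict(model: I2IModel, samples: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode argmax labels; ties break toward the lowest class index, and
    the result is invariant to how samples are batched."""
    x = np.asarray(samples, dtype=float)
    if x.ndim == 2:
        x = x[None]
    out = [np.argmax(forward(model, x[i : i + batch_size]), axis=1)
           for i in range(0, x.shape[0], batch_size)]
    return np.concatenate(out)
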