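"""Recurrent binary classifier for windowed IMU sequences.

The model is a stacked LSTM: two LSTM layers (64 and 32 hidden units by
default), dropout after the first layer, a small ReLU dense layer and a
single sigmoid output, trained with Adam on binary cross-entropy.  The
network consumes fixed-length windows of the 12-channel sensor stream
(shape ``(batch, 50, 12)``) and emits the probability that the player is
in the zone at the window's end.

Everything here is plain numpy: the forward pass, backpropagation through
time and the Adam update are implemented explicitly in float32, which is
fast enough for the session-scale problems this package targets and keeps
the training loop bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np


@dataclass
class ModelConfig:
    """Hyper-parameters of the zone classifier.

    Defaults follow the reference pipeline: window of 50 samples (5 s at
    10 Hz), 12 input channels, stacked LSTM sizes (64, 32), dropout 0.5
    after the first LSTM layer, an 8-unit ReLU dense layer, one sigmoid
    output, cross-entropy loss, Adam at learning rate 0.0025, batch size
    128 and a fixed budget of 100 epochs.
    """

    window: int = 50
    input_dim: int = 12
    recurrent_units: tuple[int, int] = (64, 32)
    dropout_after_first: float = 0.5
    dense_units: int = 8
    learning_rate: float = 0.0025
    batch_size: int = 128
    epochs: int = 100
    decision_threshold: float = 0.5
    seed: int = 0
    # evaluate test accuracy every k epochs (1 = every epoch); epochs that
    # are skipped record None in the trace
    eval_period: int = 1

    def validate(self) -> None:
        if self.window <= 0 or self.input_dim <= 0:
            raise ValueError("window and input_dim must be positive")
        if any(u <= 0 for u in self.recurrent_units) or len(self.recurrent_units) != 2:
            raise ValueError("recurrent_units must be two positive sizes")
        if not (0.0 <= self.dropout_after_first < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if min(self.dense_units, self.batch_size, self.learning_rate) <= 0:
            raise ValueError("dense_units, batch_size, learning_rate must be positive")
        if self.epochs < 0 or self.eval_period < 1:
            raise ValueError("epochs must be >= 0 and eval_period >= 1")

    def to_json(self) -> str:
        d = asdict(self)
        d["recurrent_units"] = list(self.recurrent_units)
        return json.dumps(d, indent=2)


@dataclass
class TrainTrace:
    """Per-epoch record of one training run.

    ``test_acc`` holds None for epochs where evaluation was skipped
    (``ModelConfig.eval_period`` > 1).  Wall-clock time is deliberately
    not recorded; nothing downstream may depend on it.
    """

    train_loss: list[float] = field(default_factory=list)
    test_acc: list[Optional[float]] = field(default_factory=list)
    config: Optional[ModelConfig] = None

    @property
    def epochs_run(self) -> int:
        return len(self.train_loss)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch,train_loss,test_acc\n")
            for e, (l, a) in enumerate(zip(self.train_loss, self.test_acc), start=1):
                fh.write(f"{e},{l:.6f},{'' if a is None else f'{a:.6f}'}\n")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out)).astype(np.float32)


def _orthogonal(rng: np.random.Generator, n: int, m: int) -> np.ndarray:
    a = rng.standard_normal((max(n, m), min(n, m)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    if n < m:
        q = q.T
    return q[:n, :m].astype(np.float32)


class ZoneLSTM:
    """Stacked-LSTM binary classifier with explicit numpy training.

    Gate layout in every ``(.., 4H)`` gate matrix is ``[i, f, o, u]``
    (input, forget, output, candidate).  Recurrent kernels are initialised
    orthogonally, input/dense kernels with Glorot uniform, biases at zero
    except the forget gate bias at 1.
    """

    def __init__(self, config: ModelConfig):
        config.validate()
        self.config = config
        h1, h2 = config.recurrent_units
        d = config.input_dim
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {
            "W1x": np.concatenate([_glorot(rng, d, h1) for _ in range(4)], axis=1),
            "W1h": np.concatenate([_orthogonal(rng, h1, h1) for _ in range(4)], axis=1),
            "b1": np.zeros(4 * h1, np.float32),
            "W2x": np.concatenate([_glorot(rng, h1, h2) for _ in range(4)], axis=1),
            "W2h": np.concatenate([_orthogonal(rng, h2, h2) for _ in range(4)], axis=1),
            "b2": np.zeros(4 * h2, np.float32),
            "Wd": _glorot(rng, h2, config.dense_units),
            "bd": np.zeros(config.dense_units, np.float32),
            "Wo": _glorot(rng, config.dense_units, 1),
            "bo": np.zeros(1, np.float32),
        }
        # forget-gate bias 1 stabilises early training
        self.params["b1"][h1 : 2 * h1] = 1.0
        self.params["b2"][h2 : 2 * h2] = 1.0
        # per-channel normalization, set from training windows before training
        self.norm_mean = np.zeros(d, np.float32)
        self.norm_std = np.ones(d, np.float32)
        self._adam_m: Optional[dict[str, np.ndarray]] = None
        self._adam_v: Optional[dict[str, np.ndarray]] = None
        self._adam_t = 0

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def set_normalization(self, train_inputs: np.ndarray) -> None:
        """Fit per-channel z-score statistics from training windows only."""
        x = train_inputs.reshape(-1, train_inputs.shape[-1])
        self.norm_mean = x.mean(axis=0, dtype=np.float64).astype(np.float32)
        std = x.std(axis=0, dtype=np.float64).astype(np.float32)
        self.norm_std = np.maximum(std, np.float32(1e-6))

    def _normalize(self, X: np.ndarray) -> np.ndarray:
        return ((X - self.norm_mean) / self.norm_std).astype(np.float32, copy=False)

    # ------------------------------------------------------------------
    # The recurrence works internally in time-major layout (T, B, ...) so
    # every per-step slice is contiguous; inputs/outputs at the public
    # surface stay batch-major (B, T, channels).
    @staticmethod
    def _lstm_forward(X: np.ndarray, Wx, Wh, b):
        """Run one LSTM layer over time-major (T, B, D) inputs.

        Returns hidden states plus the caches needed by backprop: cell
        states, activated gates and tanh(c), all time-major.
        """
        T, B, D = X.shape
        H = Wh.shape[0]
        G = X.reshape(T * B, D) @ Wx
        G += b
        G = G.reshape(T, B, 4 * H)
        Hs = np.empty((T, B, H), np.float32)
        Cs = np.empty((T, B, H), np.float32)
        TCs = np.empty((T, B, H), np.float32)
        A = np.empty((T, B, 4 * H), np.float32)
        h = np.zeros((B, H), np.float32)
        c = np.zeros((B, H), np.float32)
        for t in range(T):
            g = A[t]
            np.matmul(h, Wh, out=g)
            g += G[t]
            # one vectorised sigmoid over all four gate blocks;
            # tanh(x) = 2*sigmoid(2x) - 1 for the candidate block
            g[:, 3 * H :] *= 2.0
            np.negative(g, out=g)
            np.exp(g, out=g)
            g += 1.0
            np.reciprocal(g, out=g)
            g[:, 3 * H :] *= 2.0
            g[:, 3 * H :] -= 1.0
            i = g[:, :H]
            f = g[:, H : 2 * H]
            o = g[:, 2 * H : 3 * H]
            u = g[:, 3 * H :]
            cn = Cs[t]
            np.multiply(f, c, out=cn)
            cn += i * u
            c = cn
            tc = TCs[t]
            np.tanh(c, out=tc)
            h = Hs[t]
            np.multiply(o, tc, out=h)
        return Hs, Cs, TCs, A

    @staticmethod
    def _lstm_backward(X, Hs, Cs, TCs, A, Wx, Wh, dH_seq, dh_last, need_dx):
        """Backprop through one LSTM layer (all arrays time-major).

        ``dH_seq`` carries per-timestep gradients of the hidden states
        (or None); ``dh_last`` an extra gradient on the final hidden state
        (or None).  Returns (dWx, dWh, db, dX or None).
        """
        T, B, D = X.shape
        H = Wh.shape[0]
        dG = np.empty((T, B, 4 * H), np.float32)
        dh = np.zeros((B, H), np.float32)
        dc = np.zeros((B, H), np.float32)
        if dh_last is not None:
            dh += dh_last
        WhT = np.ascontiguousarray(Wh.T)
        scratch = np.empty((B, H), np.float32)
        for t in range(T - 1, -1, -1):
            if dH_seq is not None:
                dh += dH_seq[t]
            a = A[t]
            i = a[:, :H]
            f = a[:, H : 2 * H]
            o = a[:, 2 * H : 3 * H]
            u = a[:, 3 * H :]
            tc = TCs[t]
            # dc += dh * o * (1 - tc^2)
            np.multiply(tc, tc, out=scratch)
            np.subtract(1.0, scratch, out=scratch)
            scratch *= dh
            scratch *= o
            dc += scratch
            g = dG[t]
            g[:, :H] = (dc * u) * (i * (1.0 - i))
            if t > 0:
                g[:, H : 2 * H] = (dc * Cs[t - 1]) * (f * (1.0 - f))
            else:
                g[:, H : 2 * H] = 0.0
            g[:, 2 * H : 3 * H] = (dh * tc) * (o * (1.0 - o))
            g[:, 3 * H :] = (dc * i) * (1.0 - u * u)
            dh = g @ WhT
            dc *= f
        dG2 = dG.reshape(T * B, 4 * H)
        dWx = X.reshape(T * B, D).T @ dG2
        if T > 1:
            dWh = Hs[: T - 1].reshape((T - 1) * B, H).T @ dG[1:].reshape(
                (T - 1) * B, 4 * H
            )
        else:
            dWh = np.zeros_like(Wh)
        db = dG2.sum(axis=0)
        dX = (dG2 @ Wx.T).reshape(T, B, D) if need_dx else None
        return dWx, dWh, db, dX

    # ------------------------------------------------------------------
    def _forward(self, X: np.ndarray, dropout_rng: Optional[np.random.Generator]):
        """Full forward pass; returns probabilities and the backprop cache.

        ``X`` is batch-major (B, T, D); ``dropout_rng`` enables (inverted)
        dropout after the first LSTM layer — one mask per sequence, shared
        across timesteps — or pass None at evaluation time.
        """
        p = self.params
        Xtm = np.ascontiguousarray(np.swapaxes(X, 0, 1))
        H1s, C1s, TC1s, A1 = self._lstm_forward(Xtm, p["W1x"], p["W1h"], p["b1"])
        drop = self.config.dropout_after_first
        if dropout_rng is not None and drop > 0.0:
            keep = 1.0 - drop
            mask = (
                dropout_rng.random((1,) + H1s.shape[1:], dtype=np.float32) < keep
            ).astype(np.float32)
            mask /= np.float32(keep)
            X2 = H1s * mask
        else:
            mask = None
            X2 = H1s
        H2s, C2s, TC2s, A2 = self._lstm_forward(X2, p["W2x"], p["W2h"], p["b2"])
        hT = H2s[-1]
        dpre = hT @ p["Wd"] + p["bd"]
        dact = np.maximum(dpre, 0.0)
        logit = (dact @ p["Wo"] + p["bo"])[:, 0]
        prob = 1.0 / (1.0 + np.exp(-logit))
        cache = (Xtm, H1s, C1s, TC1s, A1, mask, X2, H2s, C2s, TC2s, A2, hT, dpre, dact, logit)
        return prob, cache

    def _backward(self, prob: np.ndarray, y: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        (Xtm, H1s, C1s, TC1s, A1, mask, X2, H2s, C2s, TC2s, A2, hT, dpre, dact, _) = cache
        B = Xtm.shape[1]
        dlogit = ((prob - y) / B).astype(np.float32)[:, None]
        grads: dict[str, np.ndarray] = {}
        grads["Wo"] = dact.T @ dlogit
        grads["bo"] = dlogit.sum(axis=0)
        ddact = dlogit @ p["Wo"].T
        ddact[dpre <= 0.0] = 0.0
        grads["Wd"] = hT.T @ ddact
        grads["bd"] = ddact.sum(axis=0)
        dhT = ddact @ p["Wd"].T
        dWx2, dWh2, db2, dX2 = self._lstm_backward(
            X2, H2s, C2s, TC2s, A2, p["W2x"], p["W2h"], None, dhT, True
        )
        grads["W2x"], grads["W2h"], grads["b2"] = dWx2, dWh2, db2
        if mask is not None:
            dX2 *= mask
        dWx1, dWh1, db1, _ = self._lstm_backward(
            Xtm, H1s, C1s, TC1s, A1, p["W1x"], p["W1h"], dX2, None, False
        )
        grads["W1x"], grads["W1h"], grads["b1"] = dWx1, dWh1, db1
        return grads

    # ------------------------------------------------------------------
    def _adam_step(self, grads: dict[str, np.ndarray]) -> None:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr = self.config.learning_rate
        if self._adam_m is None:
            self._adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
            self._adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._adam_t += 1
        t = self._adam_t
        corr = np.float32(lr * np.sqrt(1.0 - beta2**t) / (1.0 - beta1**t))
        for k, g in grads.items():
            g = g.astype(np.float32, copy=False)
            m = self._adam_m[k]
            v = self._adam_v[k]
            m *= beta1
            m += (1.0 - beta1) * g
            v *= beta2
            v += (1.0 - beta2) * (g * g)
            self.params[k] -= corr * m / (np.sqrt(v) + eps)

    def reset_optimizer(self) -> None:
        self._adam_m = None
        self._adam_v = None
        self._adam_t = 0

    # ------------------------------------------------------------------
    def predict_proba(self, inputs: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """In-zone probability per window (evaluation mode, no dropout)."""
        X = self._normalize(np.asarray(inputs))
        out = np.empty(len(X), np.float64)
        for s in range(0, len(X), batch_size):
            prob, _ = self._forward(X[s : s + batch_size], None)
            out[s : s + batch_size] = prob
        return out

    def save(self, prefix) -> None:
        """Persist parameters (+normalization) as .npz with a JSON config sidecar."""
        np.savez(
            f"{prefix}.npz",
            norm_mean=self.norm_mean,
            norm_std=self.norm_std,
            **self.params,
        )
        with open(f"{prefix}.json", "w") as fh:
            fh.write(self.config.to_json())

    @classmethod
    def load(cls, prefix) -> "ZoneLSTM":
        with open(f"{prefix}.json") as fh:
            d = json.load(fh)
        d["recurrent_units"] = tuple(d["recurrent_units"])
        model = cls(ModelConfig(**d))
        arrays = np.load(f"{prefix}.npz")
        for k in model.params:
            model.params[k] = arrays[k]
        model.norm_mean = arrays["norm_mean"]
        model.norm_std = arrays["norm_std"]
        return model

    def clone(self) -> "ZoneLSTM":
        """Deep copy of parameters and normalization (optimizer state reset)."""
        m = ZoneLSTM(self.config)
        m.params = {k: v.copy() for k, v in self.params.items()}
        m.norm_mean = self.norm_mean.copy()
        m.norm_std = self.norm_std.copy()
        return m


def build_model(config: Optional[ModelConfig] = None) -> ZoneLSTM:
    """Construct an untrained zone classifier from a configuration."""
    return ZoneLSTM(config if config is not None else ModelConfig())


def evaluate(model: ZoneLSTM, inputs: np.ndarray, targets: np.ndarray) -> float:
    """Fraction of windows whose thresholded probability matches the target."""
    if len(inputs) == 0:
        raise ValueError("cannot evaluate on an empty window set")
    prob = model.predict_proba(inputs)
    pred = prob >= model.config.decision_threshold
    return float(np.mean(pred == (np.asarray(targets) > 0.5)))


def _bce(prob: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(prob, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def train(
    model: ZoneLSTM,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    test_inputs: Optional[np.ndarray] = None,
    test_targets: Optional[np.ndarray] = None,
    config: Optional[ModelConfig] = None,
    reset_normalization: bool = True,
) -> TrainTrace:
    """Train the classifier in place and return its per-epoch trace.

    Normalization statistics are computed from the training windows only;
    the test set (if given) is used solely for the per-epoch accuracy in
    the trace.
    """
    cfg = config if config is not None else model.config
    cfg.validate()
    y = np.asarray(train_targets).astype(np.float32).ravel()
    if len(y) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training targets contain a single class")
    if reset_normalization:
        model.set_normalization(np.asarray(train_inputs))
    X = model._normalize(np.asarray(train_inputs))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x7E57]))
    trace = TrainTrace(config=cfg)
    n = len(X)
    bs = cfg.batch_size
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, bs):
            idx = order[s : s + bs]
            prob, cache = model._forward(X[idx], rng)
            losses.append(_bce(prob, y[idx]) * len(idx))
            grads = model._backward(prob, y[idx], cache)
            model._adam_step(grads)
        trace.train_loss.append(float(np.sum(losses) / n))
        if (
            test_inputs is not None
            and len(test_inputs) > 0
            and (epoch % cfg.eval_period == 0 or epoch == cfg.epochs)
        ):
            trace.test_acc.append(evaluate(model, test_inputs, test_targets))
        else:
            trace.test_acc.append(None)
    return trace


def retrain_from(
    source_model: ZoneLSTM,
    train_inputs: np.ndarray,
    train_targets: np.ndarray,
    test_inputs: Optional[np.ndarray] = None,
    test_targets: Optional[np.ndarray] = None,
    config: Optional[ModelConfig] = None,
) -> tuple[ZoneLSTM, TrainTrace]:
    """Warm-start training: copy all parameters from ``source_model``,
    recompute normalization from the new training windows, then train.

    Returns the retrained model and its trace.  With ``config.epochs == 0``
    the model is the source's parameter copy under the new normalization.
    """
    cfg = config if config is not None else source_model.config
    if (cfg.window, cfg.input_dim, tuple(cfg.recurrent_units), cfg.dense_units) != (
        source_model.config.window,
        source_model.config.input_dim,
        tuple(source_model.config.recurrent_units),
        source_model.config.dense_units,
    ):
        raise ValueError("source model shape-incompatible with target config")
    model = source_model.clone()
    model.config = cfg
    if cfg.epochs == 0:
        model.set_normalization(np.asarray(train_inputs))
        return model, TrainTrace(config=cfg)
    trace = train(
        model, train_inputs, train_targets, test_inputs, test_targets, cfg
    )
    return model, trace


NOT_REACHED = None


def epochs_to_threshold(
    trace_or_accs: "TrainTrace | Sequence[Optional[float]]",
    threshold: float = 0.80,
) -> Optional[int]:
    """First 1-based epoch whose test accuracy reaches ``threshold``.

    Returns None (rendered "N/A" in reports) when the trace never reaches
    the threshold.  Epochs with no recorded accuracy are skipped.
    """
    accs = (
        trace_or_accs.test_acc
        if isinstance(trace_or_accs, TrainTrace)
        else list(trace_or_accs)
    )
    for e, a in enumerate(accs, start=1):
        if a is not None and a >= threshold:
            return e
    return NOT_REACHED


def expected_param_count(config: ModelConfig) -> int:
    """Closed-form trainable-parameter count for the stacked architecture."""
    d = config.input_dim
    h1, h2 = config.recurrent_units
    k = config.dense_units
    lstm1 = 4 * (h1 * (d + h1) + h1)
    lstm2 = 4 * (h2 * (h1 + h2) + h2)
    dense = h2 * k + k
    out = k * 1 + 1
    return lstm1 + lstm2 + dense + out
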