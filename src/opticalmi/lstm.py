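"""Regression LSTM over windowed CSP feature sequences.

A small two-layer LSTM (100 and 20 hidden units by default) consumes the
N x 2m sequence feature matrix of a trial and emits a single real number
through a fully connected layer on the final hidden state.  The network is
trained as a regressor against symmetric class targets (−1/+1) with
mini-batch stochastic gradient descent with momentum and an L2 penalty; its
scalar output is the learned "temporal" feature fused with the LDA scalar
downstream.

The cell is the standard gated recurrence.  With gate pre-activations
``z = W x_t + R h_{t−1} + b`` split into input/forget/cell/output blocks:

    i = σ(z_i),  f = σ(z_f),  g = tanh(z_g),  o = σ(z_o)
    c_t = f ∘ c_{t−1} + i ∘ g
    h_t = o ∘ tanh(c_t)

with zero initial hidden and cell state.  Both the forward pass and full
backpropagation through time are implemented here in numpy; gradients are
validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.special

from .exceptions import DimensionError, ParameterError, TrainingDivergenceError

__all__ = [
    "LstmConfig",
    "LstmRegressor",
    "lstm_forward",
    "lstm_feature",
    "train_lstm_regressor",
    "loss_and_gradients",
]


@dataclass(frozen=True)
class LstmConfig:
    """Architecture and optimizer settings for the regression LSTM."""

    input_dim: int = 6
    hidden_units: tuple[int, ...] = (100, 20)
    initial_learn_rate: float = 1e-2
    l2_regularization: float = 1e-4
    momentum: float = 0.9
    max_epochs: int = 100
    batch_size: int = 16
    target_encoding: dict | None = None  # class label -> real target; default -1/+1
    init_seed: int = 0

    def validate(self) -> None:
        if not self.hidden_units:
            raise ParameterError("hidden_units must be non-empty")
        if self.initial_learn_rate <= 0 or self.l2_regularization < 0:
            raise ParameterError("learn rate must be > 0 and L2 >= 0")
        if self.max_epochs < 1 or self.batch_size < 1 or self.input_dim < 1:
            raise ParameterError("epochs, batch size and input_dim must be >= 1")


@dataclass
class LstmRegressor:
    """Trained LSTM weights (flat named arrays) plus the training loss curve.

    Parameter names: ``l{k}_W`` (4H x D input weights), ``l{k}_R`` (4H x H
    recurrent weights), ``l{k}_b`` (4H biases) per layer k, and ``fc_w``,
    ``fc_b`` for the fully connected output.  Gate block order within the 4H
    axis is input, forget, cell, output.
    """

    params: dict[str, np.ndarray]
    config: LstmConfig
    training_curve: list[float] = field(default_factory=list)

    def copy(self) -> "LstmRegressor":
        return LstmRegressor(
            {k: v.copy() for k, v in self.params.items()},
            self.config,
            list(self.training_curve),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return scipy.special.expit(x)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def initialize_lstm(config: LstmConfig) -> LstmRegressor:
    """Seeded initial weights: Glorot-uniform input maps, orthogonal
    recurrent maps, zero biases with forget-gate bias 1."""
    config.validate()
    rng = np.random.default_rng(config.init_seed)
    params: dict[str, np.ndarray] = {}
    d = config.input_dim
    for k, h in enumerate(config.hidden_units):
        limit = np.sqrt(6.0 / (d + h))
        params[f"l{k}_W"] = rng.uniform(-limit, limit, size=(4 * h, d))
        params[f"l{k}_R"] = np.vstack([_orthogonal(rng, h) for _ in range(4)])
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget gate open at init
        params[f"l{k}_b"] = b
        d = h
    h_top = config.hidden_units[-1]
    limit = np.sqrt(6.0 / (h_top + 1))
    params["fc_w"] = rng.uniform(-limit, limit, size=h_top)
    params["fc_b"] = np.zeros(1)
    return LstmRegressor(params=params, config=config)


def _forward_batch(model: LstmRegressor, X: np.ndarray, want_cache: bool):
    """X: (B, T, D) -> yhat (B,), plus per-layer caches when training.

    The input projection x_t Wᵀ is computed for all timesteps in one matmul;
    only the recurrent part runs in the timestep loop.
    """
    cfg = model.config
    B, T, D = X.shape
    if D != cfg.input_dim:
        raise DimensionError(f"sequence feature dim {D} != input_dim {cfg.input_dim}")
    layer_in = X
    caches = []
    for k, H in enumerate(cfg.hidden_units):
        W, R, b = model.params[f"l{k}_W"], model.params[f"l{k}_R"], model.params[f"l{k}_b"]
        zx = layer_in @ W.T + b  # (B, T, 4H)
        Rt = R.T
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.empty((B, T, H))
        if want_cache:
            gates = np.empty((B, T, 4 * H))  # i, f, g, o blocks
            tcs = np.empty((B, T, H))
            c_prevs = np.empty((B, T, H))
        for t in range(T):
            z = zx[:, t, :] + h @ Rt
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            if want_cache:
                gates[:, t, :H] = i
                gates[:, t, H : 2 * H] = f
                gates[:, t, 2 * H : 3 * H] = g
                gates[:, t, 3 * H :] = o
                c_prevs[:, t, :] = c
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            if want_cache:
                tcs[:, t, :] = tc
            hs[:, t, :] = h
        if want_cache:
            caches.append((layer_in, hs, gates, tcs, c_prevs))
        layer_in = hs
    yhat = layer_in[:, -1, :] @ model.params["fc_w"] + model.params["fc_b"][0]
    if want_cache:
        return yhat, layer_in[:, -1, :], caches
    return yhat


def lstm_forward(model: LstmRegressor, seq: np.ndarray) -> float:
    """Scalar regression output for one N x d sequence feature matrix."""
    seq = np.asarray(seq, dtype=float)
    if seq.ndim != 2:
        raise DimensionError("sequence must be a 2-D (windows x features) matrix")
    return float(_forward_batch(model, seq[None], want_cache=False)[0])


def lstm_feature(model: LstmRegressor, seq: np.ndarray) -> float:
    """The trained network's regression output, used as the fused feature."""
    return lstm_forward(model, seq)


def loss_and_gradients(model: LstmRegressor, X: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and its gradients for a batch.

    Returns ``(mse, grads)`` where ``grads`` maps parameter names to arrays of
    matching shape.  The L2 penalty is *not* included here; the optimizer adds
    weight decay to the gradient directly.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    B, T, _ = X.shape
    cfg = model.config
    yhat, h_top, caches = _forward_batch(model, X, want_cache=True)
    resid = yhat - y
    mse = float(np.mean(resid**2))
    dyhat = 2.0 * resid / B
    grads = {"fc_w": h_top.T @ dyhat, "fc_b": np.array([dyhat.sum()])}

    # gradient w.r.t. each layer's hidden-state sequence; top layer receives
    # loss only through the final step
    n_layers = len(cfg.hidden_units)
    dh_seq = np.zeros((B, T, cfg.hidden_units[-1]))
    dh_seq[:, -1, :] = np.outer(dyhat, model.params["fc_w"])
    for k in range(n_layers - 1, -1, -1):
        H = cfg.hidden_units[k]
        W, R = model.params[f"l{k}_W"], model.params[f"l{k}_R"]
        layer_in, hs, gates, tcs, c_prevs = caches[k]
        dz_all = np.empty((B, T, 4 * H))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i = gates[:, t, :H]
            f = gates[:, t, H : 2 * H]
            g = gates[:, t, 2 * H : 3 * H]
            o = gates[:, t, 3 * H :]
            tc = tcs[:, t, :]
            dh = dh_seq[:, t, :] + dh_next
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc**2)
            dz = dz_all[:, t, :]
            np.multiply(dc * g, i * (1.0 - i), out=dz[:, :H])
            np.multiply(dc * c_prevs[:, t, :], f * (1.0 - f), out=dz[:, H : 2 * H])
            np.multiply(dc * i, 1.0 - g**2, out=dz[:, 2 * H : 3 * H])
            np.multiply(do, o * (1.0 - o), out=dz[:, 3 * H :])
            dc_next = dc * f
            dh_next = dz @ R
        # weight gradients in single matmuls over (batch, time)
        flat_dz = dz_all.reshape(B * T, 4 * H)
        grads[f"l{k}_W"] = flat_dz.T @ layer_in.reshape(B * T, -1)
        h_prev = np.empty_like(hs)
        h_prev[:, 0, :] = 0.0
        h_prev[:, 1:, :] = hs[:, :-1, :]
        grads[f"l{k}_R"] = flat_dz.T @ h_prev.reshape(B * T, H)
        grads[f"l{k}_b"] = flat_dz.sum(axis=0)
        dh_seq = (flat_dz @ W).reshape(B, T, -1)  # lower layer's output gradient
    return mse, grads


def _encode_targets(labels, encoding: dict | None) -> np.ndarray:
    labels = [str(l) for l in labels]
    if encoding is None:
        classes = sorted(set(labels))
        if len(classes) != 2:
            raise ParameterError(
                f"default target encoding needs exactly 2 classes, got {classes}"
            )
        encoding = {classes[0]: -1.0, classes[1]: 1.0}
    try:
        return np.array([float(encoding[l]) for l in labels])
    except KeyError as e:
        raise ParameterError(f"label {e.args[0]!r} missing from target encoding") from None


def train_lstm_regressor(
    sequences, labels, config: LstmConfig = LstmConfig()
) -> LstmRegressor:
    """Train the regression LSTM on per-trial sequence feature matrices.

    Minimizes mean squared error between the network output and the encoded
    class target by mini-batch SGD with momentum; L2 regularization enters as
    weight decay on the weight matrices (not biases).  Fully deterministic
    given ``config.init_seed``.

    Raises
    ------
    TrainingDivergenceError
        If the loss becomes non-finite, naming the learn rate.
    """
    config.validate()
    seqs = [np.asarray(s, dtype=float) for s in sequences]
    if len(seqs) < 2:
        raise ParameterError("need at least 2 training sequences")
    T, D = seqs[0].shape
    for s in seqs:
        if s.shape != (T, D):
            raise DimensionError("all sequence feature matrices must share one shape")
    X = np.stack(seqs)
    y = _encode_targets(labels, config.target_encoding)
    if len(y) != len(seqs):
        raise DimensionError(f"{len(y)} labels for {len(seqs)} sequences")

    model = initialize_lstm(config)
    velocity = {k: np.zeros_like(v) for k, v in model.params.items()}
    rng = np.random.default_rng(config.init_seed + 1)
    lr, mom, l2 = config.initial_learn_rate, config.momentum, config.l2_regularization
    n = len(seqs)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        batch_losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            with np.errstate(over="ignore", invalid="ignore"):
                mse, grads = loss_and_gradients(model, X[idx], y[idx])
            if not np.isfinite(mse):
                raise TrainingDivergenceError(
                    f"non-finite training loss; initial learn rate {lr:g} too large"
                )
            batch_losses.append(mse)
            for name, g in grads.items():
                if not name.endswith("_b") and name != "fc_b":
                    g = g + l2 * model.params[name]
                velocity[name] = mom * velocity[name] - lr * g
                model.params[name] += velocity[name]
        model.training_curve.append(float(np.mean(batch_losses)))
    return model
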