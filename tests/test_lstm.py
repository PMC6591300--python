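"""LSTM regression feature: gate-equation oracle, gradients, training."""

import math

import numpy as np
import pytest

import opticalmi as om
from opticalmi.exceptions import ParameterError, TrainingDivergenceError
from opticalmi.lstm import initialize_lstm, loss_and_gradients


def _reference_forward(params, hidden_units, seq):
    """Independent step-by-step scalar evaluation of the gate equations."""

    def sig(v):
        return 1.0 / (1.0 + math.exp(-v))

    x_seq = [list(map(float, row)) for row in seq]
    for k, H in enumerate(hidden_units):
        W, R, b = params[f"l{k}_W"], params[f"l{k}_R"], params[f"l{k}_b"]
        h = [0.0] * H
        c = [0.0] * H
        outputs = []
        for x in x_seq:
            z = [
                sum(W[r][j] * x[j] for j in range(len(x)))
                + sum(R[r][j] * h[j] for j in range(H))
                + b[r]
                for r in range(4 * H)
            ]
            i = [sig(z[r]) for r in range(H)]
            f = [sig(z[H + r]) for r in range(H)]
            g = [math.tanh(z[2 * H + r]) for r in range(H)]
            o = [sig(z[3 * H + r]) for r in range(H)]
            c = [f[r] * c[r] + i[r] * g[r] for r in range(H)]
            h = [o[r] * math.tanh(c[r]) for r in range(H)]
            outputs.append(list(h))
        x_seq = outputs
    H = hidden_units[-1]
    return sum(params["fc_w"][r] * x_seq[-1][r] for r in range(H)) + params["fc_b"][0]


def test_zero_weights_output_bias(rng):
    cfg = om.LstmConfig(input_dim=3, hidden_units=(4, 2), init_seed=0)
    model = initialize_lstm(cfg)
    for name in model.params:
        model.params[name] = np.zeros_like(model.params[name])
    model.params["fc_b"] = np.array([2.5])
    assert om.lstm_forward(model, rng.standard_normal((7, 3))) == pytest.approx(2.5)


def test_forward_matches_reference_cell_oracle(rng):
    cfg = om.LstmConfig(input_dim=3, hidden_units=(2,), init_seed=5)
    model = initialize_lstm(cfg)
    seq = rng.standard_normal((3, 3))
    ref = _reference_forward(model.params, cfg.hidden_units, seq)
    assert om.lstm_forward(model, seq) == pytest.approx(ref, abs=1e-6)


def test_forward_matches_reference_two_layers(rng):
    cfg = om.LstmConfig(input_dim=4, hidden_units=(3, 2), init_seed=6)
    model = initialize_lstm(cfg)
    seq = rng.standard_normal((5, 4))
    ref = _reference_forward(model.params, cfg.hidden_units, seq)
    assert om.lstm_forward(model, seq) == pytest.approx(ref, abs=1e-6)


def test_forward_is_pure(rng):
    cfg = om.LstmConfig(input_dim=3, hidden_units=(4,), init_seed=1)
    model = initialize_lstm(cfg)
    seq = rng.standard_normal((4, 3))
    assert om.lstm_forward(model, seq) == om.lstm_forward(model, seq.copy())
    assert om.lstm_feature(model, seq) == om.lstm_forward(model, seq)


def test_gradient_check_against_finite_differences(rng):
    """Analytic BPTT gradients vs central differences on a 2-unit model."""
    cfg = om.LstmConfig(input_dim=3, hidden_units=(2,), init_seed=7)
    model = initialize_lstm(cfg)
    X = rng.standard_normal((4, 3, 3))
    y = rng.standard_normal(4)
    _, grads = loss_and_gradients(model, X, y)
    eps = 1e-6
    param_rng = np.random.default_rng(0)
    for name, arr in model.params.items():
        flat_idx = param_rng.choice(arr.size, size=min(10, arr.size), replace=False)
        for fi in flat_idx:
            idx = np.unravel_index(fi, arr.shape)
            orig = arr[idx]
            arr[idx] = orig + eps
            lp, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig - eps
            lm, _ = loss_and_gradients(model, X, y)
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[name][idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


def test_single_small_step_bounded(rng):
    """One SGD step with tiny learn rate moves weights proportionally."""
    cfg = om.LstmConfig(
        input_dim=2, hidden_units=(3,), initial_learn_rate=1e-6,
        l2_regularization=0.0, momentum=0.0, max_epochs=1, batch_size=8, init_seed=2,
    )
    seqs = [rng.standard_normal((3, 2)) for _ in range(8)]
    before = initialize_lstm(cfg).params
    after = om.train_lstm_regressor(seqs, ["a"] * 4 + ["b"] * 4, cfg).params
    _, grads = loss_and_gradients(
        initialize_lstm(cfg), np.stack(seqs), np.array([-1.0] * 4 + [1.0] * 4)
    )
    gmax = max(np.abs(g).max() for g in grads.values())
    for name in before:
        assert np.abs(after[name] - before[name]).max() <= 1e-6 * gmax * 1.001


def test_constant_targets_are_fit(rng):
    cfg = om.LstmConfig(
        input_dim=2, hidden_units=(8,), max_epochs=150, batch_size=8,
        target_encoding={"a": 0.7, "b": 0.7}, init_seed=3,
    )
    seqs = [rng.standard_normal((4, 2)) for _ in range(16)]
    model = om.train_lstm_regressor(seqs, ["a"] * 8 + ["b"] * 8, cfg)
    preds = [om.lstm_forward(model, s) for s in seqs]
    assert np.abs(np.array(preds) - 0.7).max() < 0.1


def test_training_reduces_rmse_on_mean_coded_classes(rng):
    """Class encoded in feature 1's mean; RMSE halves within 100 epochs."""
    seqs, labels = [], []
    for k, cls in enumerate(["a", "b"]):
        for _ in range(20):
            s = rng.standard_normal((5, 6)) * 0.3
            s[:, 0] += -1.0 if k == 0 else 1.0
            seqs.append(s)
            labels.append(cls)
    cfg = om.LstmConfig(init_seed=4)
    model = om.train_lstm_regressor(seqs, labels, cfg)
    curve = np.sqrt(np.asarray(model.training_curve))
    assert np.isfinite(curve).all()
    assert len(curve) == cfg.max_epochs
    assert curve[-1] < 0.5 * curve[0]
    # the learned feature separates the classes in the trained direction
    feats = np.array([om.lstm_feature(model, s) for s in seqs])
    assert feats[20:].mean() > feats[:20].mean()


def test_training_determinism(rng):
    seqs = [rng.standard_normal((4, 3)) for _ in range(10)]
    labels = ["a"] * 5 + ["b"] * 5
    cfg = om.LstmConfig(input_dim=3, hidden_units=(4,), max_epochs=10, init_seed=9)
    m1 = om.train_lstm_regressor(seqs, labels, cfg)
    m2 = om.train_lstm_regressor(seqs, labels, cfg)
    for name in m1.params:
        assert np.array_equal(m1.params[name], m2.params[name])
    assert m1.training_curve == m2.training_curve


def test_divergent_learn_rate_raises(rng):
    seqs = [rng.standard_normal((4, 3)) * 10 for _ in range(10)]
    cfg = om.LstmConfig(
        input_dim=3, hidden_units=(4,), initial_learn_rate=1e4,
        max_epochs=50, init_seed=0,
    )
    with pytest.raises(TrainingDivergenceError, match="too large"):
        om.train_lstm_regressor(seqs, ["a"] * 5 + ["b"] * 5, cfg)


def test_input_validation(rng):
    cfg = om.LstmConfig(input_dim=3, hidden_units=(4,))
    with pytest.raises(ParameterError):
        om.train_lstm_regressor([rng.standard_normal((4, 3))], ["a"], cfg)
    model = initialize_lstm(cfg)
    with pytest.raises(Exception):
        om.lstm_forward(model, rng.standard_normal((4, 5)))
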