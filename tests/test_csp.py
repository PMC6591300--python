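"""CSP filter learning against brute-force and closed-form oracles."""

import numpy as np
import pytest

import opticalmi as om
from opticalmi.csp import VARIANCE_FLOOR, _trial_covariances
from opticalmi.datasets import EpochedDataset, Trial
from opticalmi.exceptions import DimensionError, ParameterError
from opticalmi.synthetic import unmixing_direction


def _two_class(rng, n, scales_a, scales_b, n_samp=100):
    da = rng.standard_normal((n, len(scales_a), n_samp)) * np.asarray(scales_a)[None, :, None]
    db = rng.standard_normal((n, len(scales_b), n_samp)) * np.asarray(scales_b)[None, :, None]
    return EpochedDataset(
        np.concatenate([da, db]),
        np.array(["a"] * n + ["b"] * n, dtype=object),
        100.0,
    )


def test_white_noise_eigenvalues_near_half(rng):
    ds = _two_class(rng, 200, [1, 1, 1, 1, 1, 1], [1, 1, 1, 1, 1, 1])
    bank = om.learn_csp(ds)
    assert np.abs(bank.eigenvalues_full - 0.5).max() < 0.05


def test_top_filter_matches_brute_force_direction_grid(rng):
    """Variance ratio of the first filter within 1% of a 3600-point grid max."""
    ds = _two_class(rng, 200, [3.0, 1.0], [1.0, 3.0])
    bank = om.learn_csp(ds, m_pairs=1)
    covs = _trial_covariances(ds.data)
    c1, c2 = covs[:200].mean(axis=0), covs[200:].mean(axis=0)
    w = bank.W[:, 0]
    csp_ratio = (w @ c1 @ w) / (w @ c2 @ w)
    ang = np.linspace(0, np.pi, 3600, endpoint=False)
    dirs = np.stack([np.cos(ang), np.sin(ang)], axis=1)
    grid = np.einsum("ij,jk,ik->i", dirs, c1, dirs) / np.einsum(
        "ij,jk,ik->i", dirs, c2, dirs
    )
    assert csp_ratio >= 0.99 * grid.max()


def test_whitening_invariant_on_synthetic_data(mi_small):
    bank = om.learn_csp(mi_small)
    assert bank.W.shape == (8, 6)
    covs = _trial_covariances(mi_small.data)
    labels = np.array([str(l) for l in mi_small.labels])
    comp = covs[labels == "left"].mean(axis=0) + covs[labels == "right"].mean(axis=0)
    dev = bank.W_full.T @ comp @ bank.W_full - np.eye(8)
    assert np.abs(dev).max() < 1e-8


def test_eigenvalue_complementarity(mi_small):
    """Swapping the class roles gives eigenvalues 1 - lambda."""
    bank = om.learn_csp(mi_small)
    swapped = om.learn_csp(mi_small.relabel({"left": "z-left"}))  # reverses sort order
    lam = np.sort(bank.eigenvalues_full)
    lam_swapped = np.sort(1.0 - swapped.eigenvalues_full)
    assert np.allclose(lam, lam_swapped, atol=1e-8)


def test_scale_invariance(mi_small):
    bank = om.learn_csp(mi_small)
    scaled = EpochedDataset(
        mi_small.data * 37.5, mi_small.labels.copy(), mi_small.fs
    )
    bank2 = om.learn_csp(scaled)
    for j in range(bank.W.shape[1]):
        cos = abs(bank.W[:, j] @ bank2.W[:, j]) / (
            np.linalg.norm(bank.W[:, j]) * np.linalg.norm(bank2.W[:, j])
        )
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_top_filter_recovers_unmixing_direction():
    cfg = om.SyntheticConfig(
        n_trials_per_class=200, snr=10, power_ratio=4.0, mixing_seed=5, noise_seed=6
    )
    bank = om.learn_csp(om.generate_mi_dataset(cfg))
    for source in (0, 1):
        u = unmixing_direction(cfg, source)
        best = max(
            abs(bank.W[:, j] @ u) / (np.linalg.norm(bank.W[:, j]) * np.linalg.norm(u))
            for j in range(bank.n_filters)
        )
        assert best >= 0.9


def test_learn_csp_input_validation(rng, mi_small):
    one_class = mi_small.select_classes(["left"])
    with pytest.raises(ParameterError):
        om.learn_csp(one_class)
    with pytest.raises(ParameterError):
        om.learn_csp(mi_small, m_pairs=5)  # 10 filters from 8 channels


def test_apply_spatial_filter_identity_shape_and_oracle(rng, mi_small):
    bank = om.learn_csp(mi_small)
    tr = mi_small[0]
    Z = om.apply_spatial_filter(bank, tr)
    assert Z.shape == (6, 200)
    # naive triple-loop oracle on a small slice
    W, E = bank.W[:, :2], tr.data[:, :5]
    Z_small = om.apply_spatial_filter(
        om.SpatialFilterBank(W, bank.eigenvalues[:2], "left", 1), Trial(E, tr.fs)
    )
    expect = np.zeros((2, 5))
    for i in range(2):
        for j in range(5):
            for c in range(8):
                expect[i, j] += W[c, i] * E[c, j]
    assert np.allclose(Z_small, expect, atol=1e-12)
    with pytest.raises(DimensionError):
        om.apply_spatial_filter(bank, Trial(np.zeros((5, 10)), 100.0))


def test_identity_filter_returns_input(rng):
    E = rng.standard_normal((4, 30))
    bank = om.SpatialFilterBank(np.eye(4), np.full(4, 0.5), "a", 2)
    assert np.array_equal(om.apply_spatial_filter(bank, Trial(E, 100.0)), E)


def test_csp_features_formula_and_floor(rng):
    row = np.tile([1.0, -1.0], 50)  # n=100, mean 0, sum sq = 100
    y = om.csp_features(row[None, :])
    assert y[0] == pytest.approx(np.log(100 / 99), abs=1e-12)
    with pytest.warns(RuntimeWarning):
        y0 = om.csp_features(np.zeros((1, 50)))
    assert y0[0] == pytest.approx(np.log(VARIANCE_FLOOR))
    # two-pass variance oracle
    x = rng.standard_normal(257)
    mu = sum(x) / len(x)
    var = sum((v - mu) ** 2 for v in x) / (len(x) - 1)
    assert om.csp_features(x[None, :])[0] == pytest.approx(np.log(var), abs=1e-10)


def test_ovr_equals_relabeled_two_class(mi_small, nontask_small):
    three = om.EpochedDataset.concatenate([mi_small, nontask_small])
    ovr = om.learn_csp_ovr(three, "nontask")
    manual = om.learn_csp(
        three.relabel({"left": "other", "right": "other"})
    )
    # 'nontask' < 'other', so orientations agree directly
    assert np.allclose(ovr.W, manual.W)
    assert np.allclose(ovr.eigenvalues, manual.eigenvalues)
    assert ovr.positive_class == "nontask"


def test_ovr_two_class_reduces_to_csp(mi_small):
    assert np.allclose(
        om.learn_csp_ovr(mi_small, "left").W, om.learn_csp(mi_small).W
    )


def test_ovr_filters_differ_by_target(mi_small, nontask_small):
    three = om.EpochedDataset.concatenate([mi_small, nontask_small])
    w_left = om.learn_csp_ovr(three, "left").W
    w_nontask = om.learn_csp_ovr(three, "nontask").W
    assert not np.allclose(w_left, w_nontask)
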