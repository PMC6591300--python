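"""Synthetic MI-EEG generator: contracts, determinism, spectral ground truth."""

import numpy as np
import pytest
import scipy.signal

import opticalmi as om
from opticalmi.exceptions import ParameterError
from opticalmi.synthetic import SOURCE_CHANNELS


def test_mi_dataset_shape_and_balance():
    cfg = om.SyntheticConfig(
        n_channels=8, fs=100, trial_seconds=2, n_trials_per_class=50,
        mixing_seed=0, noise_seed=0,
    )
    ds = om.generate_mi_dataset(cfg)
    assert ds.data.shape == (100, 8, 200)
    labels = np.array([str(l) for l in ds.labels])
    assert (labels == "left").sum() == 50
    assert (labels == "right").sum() == 50


def test_mi_dataset_seeded_reproducibility():
    cfg = om.SyntheticConfig(n_trials_per_class=5, mixing_seed=3, noise_seed=4)
    a = om.generate_mi_dataset(cfg)
    b = om.generate_mi_dataset(cfg)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.labels, b.labels)


def test_band_power_ratio_matches_config_by_periodogram_oracle():
    """Class band-power ratio at the source channel within 15% of nominal."""
    cfg = om.SyntheticConfig(
        n_trials_per_class=200, snr=20, power_ratio=4.0, mixing_seed=3, noise_seed=4
    )
    ds = om.generate_mi_dataset(cfg)
    f, P = scipy.signal.periodogram(ds.data[:, SOURCE_CHANNELS[0], :], fs=cfg.fs, axis=-1)
    band = (f >= cfg.source_band[0]) & (f <= cfg.source_band[1])
    bp = P[:, band].sum(axis=1)
    labels = np.array([str(l) for l in ds.labels])
    ratio = bp[labels == "left"].mean() / bp[labels == "right"].mean()
    assert ratio == pytest.approx(4.0, rel=0.15)


@pytest.mark.parametrize(
    "kwargs",
    [
        {"power_ratio": 0.5},
        {"n_trials_per_class": 0},
        {"fs": 100, "trial_seconds": 2.0055},
        {"snr": -1},
        {"source_band": (40.0, 60.0), "fs": 100.0},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ParameterError):
        om.generate_mi_dataset(om.SyntheticConfig(**kwargs))


def test_nontask_trials_count_label_and_amplitude(mi_config, mi_small, nontask_small):
    cfg60 = om.SyntheticConfig(n_nontask_trials=60)
    nt = om.generate_nontask_trials(cfg60)
    assert len(nt) == 60
    assert set(str(l) for l in nt.labels) == {"nontask"}
    # blink bumps dominate: mean absolute amplitude above the paired MI config
    assert np.abs(nontask_small.data).mean() > np.abs(mi_small.data).mean()
    again = om.generate_nontask_trials(mi_config)
    assert np.array_equal(again.data, nontask_small.data)


def test_raw_with_markers_roundtrip(mi_config):
    raw = om.generate_raw_with_markers(mi_config)
    assert len(raw.markers) == 2 * mi_config.n_trials_per_class
    ds = om.epoch_trials(raw.data, raw.fs, raw.markers, raw.labels)
    # epoching recovers the embedded trials bit-identically
    ref = om.generate_mi_dataset(mi_config)
    matched = 0
    for i in range(len(ds)):
        hits = np.where((ref.data == ds.data[i]).all(axis=(1, 2)))[0]
        assert len(hits) >= 1 and str(ref.labels[hits[0]]) == str(ds.labels[i])
        matched += 1
    assert matched == len(ref)


def test_raw_marker_collision_rejected(mi_config):
    with pytest.raises(ParameterError, match="collide"):
        om.generate_raw_with_markers(mi_config, inter_cue_s=2.0)


def test_raw_seeded_reproducibility(mi_config):
    a = om.generate_raw_with_markers(mi_config)
    b = om.generate_raw_with_markers(mi_config)
    assert np.array_equal(a.data, b.data)
    assert np.array_equal(a.markers, b.markers)


def test_npz_container_roundtrip(tmp_path, mi_small):
    from opticalmi import io

    p = tmp_path / "ds.npz"
    io.save_dataset(mi_small, p)
    back = io.load_dataset(p)
    assert np.array_equal(back.data, mi_small.data)
    assert list(back.labels) == [str(l) for l in mi_small.labels]
    assert back.fs == mi_small.fs


def test_edf_roundtrip_against_mne(tmp_path):
    """Our EDF writer must be readable by an independent EDF implementation."""
    pytest.importorskip("mne")
    from opticalmi import io

    cfg = om.SyntheticConfig(n_trials_per_class=3, mixing_seed=1, noise_seed=2)
    raw = om.generate_raw_with_markers(cfg)
    n_keep = (raw.data.shape[1] // int(raw.fs)) * int(raw.fs)
    p = tmp_path / "rec.edf"
    io.write_edf(raw.data[:, :n_keep], raw.fs, p, raw.channel_names)
    data, fs, names = io.read_raw_edf(p)
    assert fs == raw.fs
    assert names == raw.channel_names
    # 16-bit quantization: relative error bounded by the digital resolution
    scale = np.abs(raw.data[:, :n_keep]).max(axis=1, keepdims=True)
    err = np.abs(data - raw.data[:, :n_keep]) / scale
    assert err.max() < 1e-3
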