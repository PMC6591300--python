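"""Epoching arithmetic, CAR, and Butterworth band-pass behavior."""

import numpy as np
import pytest
import scipy.signal

import opticalmi as om
from opticalmi.datasets import Trial
from opticalmi.exceptions import BoundaryError, ParameterError


@pytest.mark.parametrize(
    "fs,marker,start,stop",
    [
        (100, 1000, 1050, 1250),  # 0.5 s offset, 2 s epoch
        (512, 5120, 5376, 6400),
    ],
)
def test_epoch_sample_arithmetic(fs, marker, start, stop):
    rec = np.arange(2 * 8000, dtype=float).reshape(2, 8000)
    ds = om.epoch_trials(rec, fs, [marker], ["left"])
    assert ds.n_samples == stop - start
    assert np.array_equal(ds.data[0], rec[:, start:stop])


def test_epoch_beyond_end_is_boundary_error():
    rec = np.zeros((2, 1000))
    with pytest.raises(BoundaryError, match="900"):
        om.epoch_trials(rec, 100, [900], ["left"])


def test_car_two_channel_closed_form(rng):
    a, b = rng.standard_normal(50), rng.standard_normal(50)
    out = om.common_average_reference(Trial(np.vstack([a, b]), 100.0))
    assert np.allclose(out.data[0], (a - b) / 2)
    assert np.allclose(out.data[1], (b - a) / 2)


def test_car_zero_mean_and_idempotent(rng):
    tr = Trial(rng.standard_normal((6, 120)), 100.0)
    out = om.common_average_reference(tr)
    assert np.abs(out.data.mean(axis=0)).max() < 1e-12
    twice = om.common_average_reference(out)
    assert np.allclose(twice.data, out.data)


def test_car_single_channel_rejected():
    with pytest.raises(ParameterError):
        om.common_average_reference(Trial(np.zeros((1, 10)), 100.0))


def test_bandpass_passband_and_stopband_oracle():
    """Compare against the analytic Butterworth magnitude response."""
    fs, n = 100.0, 2000
    t = np.arange(n) / fs
    spec = om.BandpassSpec()
    sos = scipy.signal.butter(spec.order, [spec.low, spec.high], "bandpass", fs=fs, output="sos")
    for freq in (20.0, 2.0):
        x = np.sin(2 * np.pi * freq * t)
        out = om.bandpass_filter(Trial(x[None, :], fs), spec).data[0]
        mid = slice(n // 10, -n // 10)
        gain = np.sqrt(np.mean(out[mid] ** 2) / np.mean(x[mid] ** 2))
        _, h = scipy.signal.sosfreqz(sos, worN=[freq], fs=fs)
        expected = np.abs(h[0]) ** 2  # forward-backward squares the response
        assert gain == pytest.approx(expected, abs=0.03)
    # spec's stated contracts
    x20 = om.bandpass_filter(Trial(np.sin(2 * np.pi * 20 * t)[None, :], fs), spec).data[0]
    g20 = np.sqrt(np.mean(x20[n // 10 : -n // 10] ** 2) * 2)
    assert 0.9 <= g20 <= 1.05
    x2 = om.bandpass_filter(Trial(np.sin(2 * np.pi * 2 * t)[None, :], fs), spec).data[0]
    g2 = np.sqrt(np.mean(x2[n // 10 : -n // 10] ** 2) * 2)
    assert 20 * np.log10(1.0 / g2) >= 20


def test_bandpass_kills_dc():
    tr = Trial(np.full((3, 400), 7.5), 100.0)
    out = om.bandpass_filter(tr)
    assert np.abs(out.data).max() < 1e-6 * 7.5


def test_bandpass_invalid_cutoff_rejected():
    with pytest.raises(ParameterError):
        om.bandpass_filter(Trial(np.zeros((2, 100)), 50.0), om.BandpassSpec(high=30.0))


def test_filter_linearity(rng):
    x = rng.standard_normal((4, 300))
    y = rng.standard_normal((4, 300))
    fa = om.bandpass_filter(Trial(2.0 * x + 3.0 * y, 100.0)).data
    fb = 2.0 * om.bandpass_filter(Trial(x, 100.0)).data + 3.0 * om.bandpass_filter(
        Trial(y, 100.0)
    ).data
    assert np.allclose(fa, fb, rtol=1e-8, atol=1e-10)


def test_car_and_bandpass_commute(rng):
    tr = Trial(rng.standard_normal((5, 250)), 100.0)
    a = om.bandpass_filter(om.common_average_reference(tr))
    b = om.common_average_reference(om.bandpass_filter(tr))
    assert np.allclose(a.data, b.data, atol=1e-9)


def test_preprocess_dataset_matches_per_trial_path(mi_small):
    pp = om.preprocess_dataset(mi_small)
    manual = om.bandpass_filter(om.common_average_reference(mi_small[0]))
    assert np.allclose(pp.data[0], manual.data, atol=1e-9)
    assert np.isfinite(pp.data).all()


def test_bciciv_style_mat_reader(tmp_path, rng):
    """Competition-style cnt/mrk/nfo container -> recording + markers."""
    import scipy.io

    from opticalmi import io

    rec = rng.standard_normal((3, 1000)) * 50
    mat = {
        "cnt": np.round(rec.T / 0.1).astype(np.int16),  # time x ch, 0.1 uV units
        "mrk": {"pos": np.array([100, 400, 700]), "y": np.array([-1, 1, -1])},
        "nfo": {
            "fs": 100.0,
            "classes": np.array(["left", "right"], dtype=object),
            "clab": np.array(["C3", "Cz", "C4"], dtype=object),
        },
    }
    p = tmp_path / "subject.mat"
    scipy.io.savemat(p, mat)
    out, fs, pos, labels, ch = io.read_bciciv_mat(p)
    assert out.shape == (3, 1000) and fs == 100.0
    assert list(pos) == [100, 400, 700]
    assert list(labels) == ["left", "right", "left"]
    assert ch == ["C3", "Cz", "C4"]
    assert np.abs(out - np.round(rec / 0.1) * 0.1).max() < 1e-9
    ds = om.epoch_trials(out, fs, pos, labels)
    assert ds.data.shape == (3, 3, 200)
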