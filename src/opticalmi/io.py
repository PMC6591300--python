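"""Reading and writing EEG containers.

Three formats are supported:

* an internal ``.npz`` fixture container for :class:`~opticalmi.datasets.EpochedDataset`
  (named arrays ``data``, ``labels``, ``fs``, ``channel_names``);
* EDF for continuous recordings — reading goes through :mod:`mne` when it is
  installed; writing uses a minimal built-in EDF encoder (fixed-width ASCII
  header, 16-bit samples, one-second data records) so that recordings can be
  exchanged with standard EEG tools;
* BCI-Competition-IV-style MATLAB containers (``cnt``/``mrk``/``nfo``
  variables) via :func:`scipy.io.loadmat`.
"""

from __future__ import annotations

import numpy as np
import scipy.io

from .datasets import EpochedDataset
from .exceptions import ParameterError

__all__ = [
    "save_dataset",
    "load_dataset",
    "write_edf",
    "read_raw_edf",
    "read_bciciv_mat",
]


# ---------------------------------------------------------------------------
# internal npz container
# ---------------------------------------------------------------------------

def save_dataset(dataset: EpochedDataset, path) -> None:
    """Write an :class:`EpochedDataset` to an ``.npz`` archive."""
    np.savez_compressed(
        path,
        data=dataset.data,
        labels=np.array([str(l) for l in dataset.labels]),
        fs=np.array(dataset.fs),
        channel_names=np.array(dataset.channel_names),
    )


def load_dataset(path) -> EpochedDataset:
    """Read an :class:`EpochedDataset` written by :func:`save_dataset`."""
    with np.load(path, allow_pickle=False) as z:
        return EpochedDataset(
            z["data"],
            z["labels"].astype(object),
            float(z["fs"]),
            [str(c) for c in z["channel_names"]],
        )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _ascii_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: np.ndarray, fs: float, path, channel_names=None) -> None:
    """Write a continuous ``channels x samples`` recording (µV) as plain EDF.

    The sampling rate must be a positive integer and the number of samples a
    multiple of ``fs`` (whole one-second data records).  Samples are scaled to
    the signed 16-bit digital range per channel, so a round trip quantizes
    amplitudes to about ``max|x| / 32767``.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2:
        raise ParameterError("recording must be channels x samples")
    if fs <= 0 or fs != int(fs):
        raise ParameterError(f"EDF export requires an integer sampling rate, got {fs}")
    fs = int(fs)
    n_ch, n_samp = recording.shape
    if n_samp % fs != 0:
        raise ParameterError(
            f"number of samples ({n_samp}) must be a multiple of fs ({fs})"
        )
    n_records = n_samp // fs
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]

    # symmetric physical range per channel keeps digital zero at physical zero
    phys_max = np.maximum(np.abs(recording).max(axis=1), 1e-6)
    dig_max = 32767
    digital = np.round(recording / phys_max[:, None] * dig_max).astype("<i2")

    header = b"".join(
        [
            _ascii_field(0, 8),  # version
            _ascii_field("X X X X", 80),  # patient id
            _ascii_field("Startdate X X X X", 80),  # recording id
            _ascii_field("01.01.00", 8),
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (1 + n_ch), 8),
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),  # record duration, seconds
            _ascii_field(n_ch, 4),
        ]
    )
    per_signal = [
        b"".join(_ascii_field(name[:16], 16) for name in channel_names),
        b"".join(_ascii_field("", 80) for _ in range(n_ch)),
        b"".join(_ascii_field("uV", 8) for _ in range(n_ch)),
        b"".join(_ascii_field(f"{-m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_ascii_field(f"{m:.6g}"[:8], 8) for m in phys_max),
        b"".join(_ascii_field(-dig_max, 8) for _ in range(n_ch)),
        b"".join(_ascii_field(dig_max, 8) for _ in range(n_ch)),
        b"".join(_ascii_field("", 80) for _ in range(n_ch)),
        b"".join(_ascii_field(fs, 8) for _ in range(n_ch)),
        b"".join(_ascii_field("", 32) for _ in range(n_ch)),
    ]
    with open(path, "wb") as f:
        f.write(header)
        for block in per_signal:
            f.write(block)
        for r in range(n_records):
            chunk = digital[:, r * fs : (r + 1) * fs]  # signal-major within record
            f.write(chunk.tobytes())


def read_raw_edf(path):
    """Read a continuous EDF recording; returns ``(data µV, fs, channel_names)``.

    Requires :mod:`mne`.
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne returns volts
    return data, float(raw.info["sfreq"]), list(raw.ch_names)


# ---------------------------------------------------------------------------
# BCI-Competition-IV-style MATLAB container
# ---------------------------------------------------------------------------

def read_bciciv_mat(path):
    """Read a BCI-Competition-IV-style continuous ``.mat`` container.

    Expects the competition's variables: ``cnt`` (time x channels, 0.1 µV
    units), ``mrk.pos``/``mrk.y`` (cue positions and ±1 class codes) and
    ``nfo.fs``/``nfo.classes``.  Returns ``(recording µV channels x samples,
    fs, marker_positions, marker_labels, channel_names)``.
    """
    m = scipy.io.loadmat(path, squeeze_me=True, struct_as_record=False)
    if "cnt" not in m or "mrk" not in m or "nfo" not in m:
        raise ParameterError("not a BCI-Competition-IV-style container (need cnt, mrk, nfo)")
    cnt = np.asarray(m["cnt"], dtype=float).T * 0.1  # to µV, channels x samples
    nfo, mrk = m["nfo"], m["mrk"]
    fs = float(np.squeeze(nfo.fs))
    classes = [str(c) for c in np.atleast_1d(nfo.classes)]
    pos = np.atleast_1d(np.asarray(mrk.pos, dtype=int).squeeze())
    y = np.atleast_1d(np.asarray(mrk.y, dtype=float).squeeze())
    labels = np.array([classes[0] if v < 0 else classes[1] for v in y], dtype=object)
    try:
        ch_names = [str(c) for c in np.atleast_1d(nfo.clab)]
    except AttributeError:
        ch_names = [f"ch{i}" for i in range(cnt.shape[0])]
    return cnt, fs, pos, labels, ch_names
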