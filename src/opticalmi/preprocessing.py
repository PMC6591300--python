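"""Epoching, common average referencing and band-pass filtering.

Continuous recordings are cut into trials starting a fixed latency after each
visual cue (default 0.5 s, 2 s long), re-referenced to the common average, and
band-pass filtered to the mu/beta range (7–30 Hz Butterworth) where
motor-imagery desynchronization lives.  Filtering is zero-phase (4th-order
sections applied forward and backward with reflective edge padding), which
avoids group-delay distortion on short epochs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

from .datasets import EpochedDataset, Trial
from .exceptions import BoundaryError, ParameterError

__all__ = [
    "BandpassSpec",
    "epoch_trials",
    "common_average_reference",
    "bandpass_filter",
    "preprocess_dataset",
]


@dataclass(frozen=True)
class BandpassSpec:
    """Butterworth band-pass specification.

    ``low``/``high`` are the −3 dB passband edges in Hz of the analog
    prototype; ``order`` is the prototype order (the effective order doubles
    under zero-phase filtering).
    """

    low: float = 7.0
    high: float = 30.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0 < self.low < self.high:
            raise ParameterError(f"need 0 < low < high, got {self.low}, {self.high}")
        if self.high >= fs / 2:
            raise ParameterError(
                f"high cutoff {self.high} Hz must be below Nyquist ({fs / 2} Hz)"
            )
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")


def epoch_trials(
    recording: np.ndarray,
    fs: float,
    markers,
    labels=None,
    offset_s: float = 0.5,
    length_s: float = 2.0,
    channel_names=None,
) -> EpochedDataset:
    """Cut a continuous recording into fixed-length trials after each cue.

    Each marker ``m`` yields the half-open sample span
    ``[m + round(offset_s*fs), m + round(offset_s*fs) + round(length_s*fs))``.

    Parameters
    ----------
    recording : ndarray, shape (n_channels, n_samples)
    fs : float
    markers : sequence of int
        Cue-onset sample indices (0-based).
    labels : sequence of str, optional
        Per-marker class ids; unlabeled trials get ``"unlabeled"``.
    offset_s, length_s : float
        Epoch start latency after the cue, and epoch duration, in seconds.

    Raises
    ------
    BoundaryError
        If any epoch extends beyond the recording, naming the marker.
    """
    recording = np.asarray(recording, dtype=float)
    if recording.ndim != 2:
        raise ParameterError("recording must be channels x samples")
    markers = np.asarray(markers, dtype=int)
    if labels is None:
        labels = ["unlabeled"] * len(markers)
    if len(labels) != len(markers):
        raise ParameterError(f"{len(labels)} labels for {len(markers)} markers")
    off = int(round(offset_s * fs))
    length = int(round(length_s * fs))
    if length < 1:
        raise ParameterError(f"epoch length {length_s} s is below one sample at fs={fs}")

    n_total = recording.shape[1]
    epochs = []
    for m in markers:
        start, stop = m + off, m + off + length
        if start < 0 or stop > n_total:
            raise BoundaryError(
                f"epoch [{start}, {stop}) for marker at sample {m} exceeds "
                f"recording bounds [0, {n_total})"
            )
        epochs.append(recording[:, start:stop])
    return EpochedDataset(
        np.stack(epochs) if epochs else np.empty((0, recording.shape[0], length)),
        np.asarray(list(labels), dtype=object),
        fs,
        list(channel_names) if channel_names else [],
    )


def common_average_reference(trial: Trial) -> Trial:
    """Subtract the instantaneous mean across channels from every channel.

    The output has exact zero mean over channels at every sample.  Undefined
    for single-channel data.
    """
    if trial.n_channels < 2:
        raise ParameterError("common average reference needs at least 2 channels")
    data = trial.data - trial.data.mean(axis=0, keepdims=True)
    return Trial(data, trial.fs, trial.label)


def _design_sos(spec: BandpassSpec, fs: float):
    return scipy.signal.butter(
        spec.order, [spec.low, spec.high], btype="bandpass", fs=fs, output="sos"
    )


def bandpass_filter(trial: Trial, spec: BandpassSpec = BandpassSpec()) -> Trial:
    """Band-pass filter each channel independently.

    Zero-phase (``sosfiltfilt`` with even-reflection padding) when
    ``spec.zero_phase``; causal ``sosfilt`` otherwise.
    """
    spec.validate(trial.fs)
    sos = _design_sos(spec, trial.fs)
    if spec.zero_phase:
        out = scipy.signal.sosfiltfilt(sos, trial.data, axis=1, padtype="even")
    else:
        out = scipy.signal.sosfilt(sos, trial.data, axis=1)
    return Trial(out, trial.fs, trial.label)


def preprocess_dataset(
    dataset: EpochedDataset, spec: BandpassSpec = BandpassSpec(), car: bool = True
) -> EpochedDataset:
    """CAR then band-pass every trial; shapes and labels are preserved."""
    spec.validate(dataset.fs)
    data = dataset.data
    if car:
        data = data - data.mean(axis=1, keepdims=True)
    sos = _design_sos(spec, dataset.fs)
    if spec.zero_phase:
        data = scipy.signal.sosfiltfilt(sos, data, axis=2, padtype="even")
    else:
        data = scipy.signal.sosfilt(sos, data, axis=2)
    return EpochedDataset(data, dataset.labels.copy(), dataset.fs, list(dataset.channel_names))
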