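"""Synthetic motor-imagery EEG with known ground truth.

Every downstream stage is testable without external recordings: trials carry
class-lateralized narrow-band (default 8–12 Hz) oscillatory sources at two
designated source channels, mixed into all channels through a reproducible
near-orthogonal full-rank mixing matrix, on top of 1/f background noise.
Class structure mirrors event-related desynchronization in spirit: the two
classes differ by a band-power ratio (``power_ratio``) at mirrored source
channels, which CSP is designed to pick up.  Non-task trials emulate eye
blinks and rest: no lateralized sources, sporadic high-amplitude
low-frequency bumps with a frontal-dominant topography.

The generators are pure functions of their seeds; identical configs give
bit-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import EpochedDataset
from .exceptions import ParameterError

__all__ = [
    "SyntheticConfig",
    "RawRecording",
    "mixing_matrix",
    "unmixing_direction",
    "generate_mi_dataset",
    "generate_nontask_trials",
    "generate_raw_with_markers",
    "SOURCE_CHANNELS",
]

#: EEG channels at which the two class-lateralized sources project dominantly.
SOURCE_CHANNELS = (0, 1)

_SOURCE_AMP = 1.0  # base source amplitude, µV-scale
_AM_DEPTH = 0.3  # amplitude-modulation depth of the source envelope
_LATENT_NOISE_AMP = 0.2  # weak extra latent sources exercising the full mixing
_BLINK_AMP_FACTOR = 3.5  # blink peak relative to the strong source amplitude


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of the synthetic MI datasets.

    ``power_ratio`` is the between-class ratio of narrow-band power at each
    source channel (>= 1); ``snr`` is the ratio of base source amplitude to
    background-noise standard deviation; ``noise_exponent`` is the 1/f^a
    slope of the background spectrum.
    """

    n_channels: int = 8
    fs: float = 100.0
    trial_seconds: float = 2.0
    n_trials_per_class: int = 50
    classes: tuple[str, str] = ("left", "right")
    nontask_label: str = "nontask"
    n_nontask_trials: int | None = None  # default: total MI trial count
    source_band: tuple[float, float] = (8.0, 12.0)
    power_ratio: float = 4.0
    noise_exponent: float = 1.0
    snr: float = 3.0
    mixing_seed: int = 0
    noise_seed: int = 0

    def validate(self) -> None:
        n_samp = self.fs * self.trial_seconds
        if abs(n_samp - round(n_samp)) > 1e-9:
            raise ParameterError(
                f"fs*trial_seconds must be an integer sample count, got {n_samp}"
            )
        if self.n_channels < 2:
            raise ParameterError("need at least 2 channels")
        if self.n_trials_per_class < 1:
            raise ParameterError("need at least 1 trial per class")
        if self.power_ratio < 1:
            raise ParameterError(f"power_ratio must be >= 1, got {self.power_ratio}")
        if not (0 < self.source_band[0] < self.source_band[1] < self.fs / 2):
            raise ParameterError(f"invalid source band {self.source_band} at fs={self.fs}")
        if self.snr <= 0:
            raise ParameterError("snr must be positive")
        if len(self.classes) != 2:
            raise ParameterError("exactly two MI classes are required")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.trial_seconds))


@dataclass
class RawRecording:
    """A continuous multi-channel record with cue-onset markers."""

    data: np.ndarray  # channels x samples
    fs: float
    markers: np.ndarray  # cue-onset sample indices
    labels: np.ndarray
    channel_names: list[str]


def mixing_matrix(config: SyntheticConfig) -> np.ndarray:
    """The dataset's full-rank source-to-channel mixing matrix.

    Near-identity with small random off-diagonal coupling, orthogonalized by
    QR, so each latent source projects dominantly onto its own channel while
    remaining mixed into all of them.  Deterministic from ``mixing_seed``.
    """
    rng = np.random.default_rng(config.mixing_seed)
    c = config.n_channels
    m = np.eye(c) + 0.08 * rng.standard_normal((c, c))
    q, r = np.linalg.qr(m)
    return q * np.sign(np.diag(r))


def unmixing_direction(config: SyntheticConfig, source: int) -> np.ndarray:
    """Row of the inverse mixing matrix recovering latent source ``source``."""
    return np.linalg.inv(mixing_matrix(config))[source]


def _pink_noise(rng: np.random.Generator, shape, exponent: float, fs: float) -> np.ndarray:
    """Unit-variance 1/f^exponent Gaussian noise along the last axis."""
    n = shape[-1]
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gain = np.ones_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    gain[0] = 0.0
    out = np.fft.irfft(spec * gain, n=n, axis=-1)
    sd = out.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def _source_wave(rng: np.random.Generator, config: SyntheticConfig, amp: float) -> np.ndarray:
    t = np.arange(config.n_samples) / config.fs
    f = rng.uniform(*config.source_band)
    phase = rng.uniform(0, 2 * np.pi)
    f_am = rng.uniform(0.3, 1.0)
    phase_am = rng.uniform(0, 2 * np.pi)
    env = 1.0 + _AM_DEPTH * np.sin(2 * np.pi * f_am * t + phase_am)
    return amp * env * np.sin(2 * np.pi * f * t + phase)


def _mi_trial(rng, config: SyntheticConfig, A: np.ndarray, class_index: int) -> np.ndarray:
    c, n = config.n_channels, config.n_samples
    strong = _SOURCE_AMP * np.sqrt(config.power_ratio)
    amps = [strong, _SOURCE_AMP] if class_index == 0 else [_SOURCE_AMP, strong]
    latent = np.zeros((c, n))
    latent[SOURCE_CHANNELS[0]] = _source_wave(rng, config, amps[0])
    latent[SOURCE_CHANNELS[1]] = _source_wave(rng, config, amps[1])
    if c > 2:
        latent[2:] = _LATENT_NOISE_AMP * _pink_noise(
            rng, (c - 2, n), config.noise_exponent, config.fs
        )
    noise = (_SOURCE_AMP / config.snr) * _pink_noise(
        rng, (c, n), config.noise_exponent, config.fs
    )
    return A @ latent + noise


def generate_mi_dataset(config: SyntheticConfig = SyntheticConfig()) -> EpochedDataset:
    """Balanced two-class MI dataset.

    Class ``classes[0]`` has the stronger source at channel
    ``SOURCE_CHANNELS[0]``, class ``classes[1]`` mirrored at
    ``SOURCE_CHANNELS[1]``; the in-band power ratio between classes at each
    source channel equals ``power_ratio`` (up to mixing cross-talk and
    noise).
    """
    config.validate()
    A = mixing_matrix(config)
    rng = np.random.default_rng(config.noise_seed)
    trials, labels = [], []
    for k, cls in enumerate(config.classes):
        for _ in range(config.n_trials_per_class):
            trials.append(_mi_trial(rng, config, A, k))
            labels.append(cls)
    return EpochedDataset(np.stack(trials), np.array(labels, dtype=object), config.fs)


def generate_nontask_trials(config: SyntheticConfig = SyntheticConfig()) -> EpochedDataset:
    """Non-task trials: background noise plus sporadic eye-blink-like bumps.

    No lateralized band sources; each trial carries at least one Gaussian
    bump (width ~0.1 s, frontal-dominant topography) whose peak amplitude is
    ``3.5x`` the strong source amplitude, emulating blinks/eye movements at
    rest.
    """
    config.validate()
    n_trials = (
        config.n_nontask_trials
        if config.n_nontask_trials is not None
        else 2 * config.n_trials_per_class
    )
    if n_trials < 1:
        raise ParameterError("need at least 1 non-task trial")
    c, n = config.n_channels, config.n_samples
    topo = np.exp(-np.arange(c) / 2.0)  # frontal-dominant blink topography
    blink_amp = _BLINK_AMP_FACTOR * _SOURCE_AMP * np.sqrt(config.power_ratio)
    rng = np.random.default_rng(config.noise_seed + 77003)
    t = np.arange(n) / config.fs
    trials = []
    for _ in range(n_trials):
        x = (_SOURCE_AMP / config.snr) * _pink_noise(
            rng, (c, n), config.noise_exponent, config.fs
        )
        n_bumps = 1 + rng.poisson(1.5)
        for _b in range(n_bumps):
            center = rng.uniform(0.1, config.trial_seconds - 0.1)
            width = rng.uniform(0.08, 0.15)
            bump = blink_amp * np.exp(-0.5 * ((t - center) / width) ** 2)
            x += topo[:, None] * bump[None, :]
        trials.append(x)
    return EpochedDataset(
        np.stack(trials),
        np.array([config.nontask_label] * n_trials, dtype=object),
        config.fs,
    )


def generate_raw_with_markers(
    config: SyntheticConfig = SyntheticConfig(),
    offset_s: float = 0.5,
    inter_cue_s: float = 3.2,
) -> RawRecording:
    """One continuous record with cue markers embedding MI trials exactly.

    Epoching the record at ``(cue + offset_s, trial_seconds)`` recovers the
    embedded trials bit-identically.  ``inter_cue_s`` below the epoch span
    (``offset_s + trial_seconds``) would make epochs collide and raises.
    """
    config.validate()
    span = offset_s + config.trial_seconds
    if inter_cue_s < span:
        raise ParameterError(
            f"inter-cue interval {inter_cue_s} s below epoch span {span} s: markers collide"
        )
    epochs = generate_mi_dataset(config)
    # deterministic label interleaving for a natural cue sequence
    order_rng = np.random.default_rng(config.noise_seed + 41011)
    order = order_rng.permutation(len(epochs))

    fs = config.fs
    pre = int(round(1.0 * fs))
    step = int(round(inter_cue_s * fs))
    off = int(round(offset_s * fs))
    n_len = config.n_samples
    total = pre + step * len(epochs) + int(round(1.0 * fs))
    noise_rng = np.random.default_rng(config.noise_seed + 52019)
    record = (_SOURCE_AMP / config.snr) * _pink_noise(
        noise_rng, (config.n_channels, total), config.noise_exponent, fs
    )
    markers, labels = [], []
    for j, idx in enumerate(order):
        cue = pre + j * step
        start = cue + off
        record[:, start : start + n_len] = epochs.data[idx]
        markers.append(cue)
        labels.append(epochs.labels[idx])
    return RawRecording(
        data=record,
        fs=fs,
        markers=np.asarray(markers, dtype=int),
        labels=np.asarray(labels, dtype=object),
        channel_names=[f"ch{i}" for i in range(config.n_channels)],
    )
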