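"""In-memory containers for epoched multi-channel EEG data.

The two central types are :class:`Trial` (one channels x samples epoch) and
:class:`EpochedDataset` (a stack of equally shaped trials with labels, a
sampling rate and channel names).  Everything downstream of epoching operates
on these containers, so file-format concerns stay in :mod:`opticalmi.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError, ParameterError

__all__ = ["Trial", "EpochedDataset"]


@dataclass
class Trial:
    """A single EEG epoch.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    label : str or None
        Class id (e.g. ``"left"``), or ``None`` for an unlabeled trial.
    """

    data: np.ndarray
    fs: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ParameterError(
                f"trial data must be 2-D channels x samples, got shape {self.data.shape}"
            )
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass
class EpochedDataset:
    """A labeled set of equally shaped EEG trials.

    Parameters
    ----------
    data : ndarray, shape (n_trials, n_channels, n_samples)
    labels : sequence of str, length n_trials
    fs : float
        Common sampling rate in Hz.
    channel_names : list of str, optional
        Defaults to ``["ch0", "ch1", ...]``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            raise ParameterError(
                f"dataset array must be (n_trials, n_channels, n_samples), got {self.data.shape}"
            )
        if len(self.labels) != self.data.shape[0]:
            raise DimensionError(
                f"{len(self.labels)} labels for {self.data.shape[0]} trials"
            )
        if self.fs <= 0:
            raise ParameterError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.data.shape[1])]
        if len(self.channel_names) != self.data.shape[1]:
            raise DimensionError(
                f"{len(self.channel_names)} channel names for {self.data.shape[1]} channels"
            )

    # -- basic protocol -----------------------------------------------------
    def __len__(self) -> int:
        return self.data.shape[0]

    def __getitem__(self, i: int) -> Trial:
        return Trial(self.data[i], self.fs, self.labels[i])

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> list[str]:
        """Distinct labels in sorted order."""
        return sorted({str(l) for l in self.labels})

    def trials(self):
        """Iterate over :class:`Trial` views."""
        for i in range(len(self)):
            yield self[i]

    # -- manipulation -------------------------------------------------------
    def subset(self, indices) -> "EpochedDataset":
        """A new dataset restricted to ``indices`` (order preserved)."""
        idx = np.asarray(indices)
        return EpochedDataset(
            self.data[idx].copy(),
            self.labels[idx].copy(),
            self.fs,
            list(self.channel_names),
        )

    def select_classes(self, classes) -> "EpochedDataset":
        keep = [i for i, l in enumerate(self.labels) if str(l) in set(classes)]
        return self.subset(keep)

    def relabel(self, mapping: dict) -> "EpochedDataset":
        """A copy with labels mapped through ``mapping`` (missing keys kept)."""
        new = np.array([mapping.get(str(l), str(l)) for l in self.labels], dtype=object)
        return EpochedDataset(self.data.copy(), new, self.fs, list(self.channel_names))

    @staticmethod
    def concatenate(datasets) -> "EpochedDataset":
        datasets = list(datasets)
        first = datasets[0]
        for d in datasets[1:]:
            if d.data.shape[1:] != first.data.shape[1:] or d.fs != first.fs:
                raise DimensionError("datasets to concatenate must share shape and fs")
        return EpochedDataset(
            np.concatenate([d.data for d in datasets], axis=0),
            np.concatenate([d.labels for d in datasets]),
            first.fs,
            list(first.channel_names),
        )
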