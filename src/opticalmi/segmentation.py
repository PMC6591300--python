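"""Sliding-window segmentation of trials into LSTM sequence features.

Each trial is cut into N overlapping windows of length l with overlap t
(defaults: l = 25% and t = 5% of the trial length).  Window j starts at
j·(l−t); if the last regular window stops short of the trial end, one final
window is re-anchored to end exactly at the last sample, so every sample is
used without padding.  Each window is spatially filtered by the segment-level
CSP bank and reduced to its 2m log-variance features, giving an N x 2m
feature matrix — the sequence input of the LSTM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .csp import SpatialFilterBank, apply_spatial_filter, csp_features
from .datasets import Trial
from .exceptions import ParameterError

__all__ = [
    "WindowParams",
    "default_window_params",
    "segment_trial",
    "window_starts",
    "build_sequence_features",
]


@dataclass(frozen=True)
class WindowParams:
    """Window length ``l``, overlap ``t`` and trial length ``S``, in samples."""

    l: int
    t: int
    S: int

    def __post_init__(self) -> None:
        if not (0 < self.t < self.l <= self.S):
            raise ParameterError(
                f"need 0 < t < l <= S, got l={self.l}, t={self.t}, S={self.S}"
            )


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def default_window_params(S: int) -> WindowParams:
    """Window length 25% and overlap 5% of the trial length (half-up rounding)."""
    if S < 8:
        raise ParameterError(f"trial length {S} too short for default windows")
    return WindowParams(l=_round_half_up(0.25 * S), t=_round_half_up(0.05 * S), S=S)


def window_starts(p: WindowParams) -> np.ndarray:
    """Start indices of the N windows (half-open spans [s, s+l))."""
    step = p.l - p.t
    starts = list(range(0, p.S - p.l + 1, step))
    if starts[-1] + p.l < p.S:
        starts.append(p.S - p.l)  # end-aligned final window: full coverage
    return np.asarray(starts, dtype=int)


def segment_trial(trial: Trial, p: WindowParams) -> list[np.ndarray]:
    """Cut a trial into its N windows, each ``channels x l``."""
    if trial.n_samples != p.S:
        raise ParameterError(
            f"window params are for S={p.S} but trial has {trial.n_samples} samples"
        )
    return [trial.data[:, s : s + p.l] for s in window_starts(p)]


def build_sequence_features(
    trial: Trial, p: WindowParams, bank: SpatialFilterBank
) -> np.ndarray:
    """Per-trial N x 2m sequence feature matrix (rows in window order)."""
    rows = [
        csp_features(apply_spatial_filter(bank, Trial(w, trial.fs, trial.label)))
        for w in segment_trial(trial, p)
    ]
    return np.vstack(rows)
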