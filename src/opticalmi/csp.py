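"""Common spatial patterns: supervised spatial filtering for two-class EEG.

CSP finds directions w maximizing the ratio of class variances.  With
trace-normalized per-trial covariances C = E Eᵀ / tr(E Eᵀ) and class means
C̄₁, C̄₂, the filters solve the generalized eigenproblem

    C̄₁ w = λ (C̄₁ + C̄₂) w,

whose eigenvalues λ ∈ (0, 1) are the fraction of (whitened) variance captured
from class 1.  The filter bank keeps the m eigenvectors with the largest and
the m with the smallest eigenvalues (2m filters; 2m = 6 by default).  Features
are log-variances of the spatially filtered signal: y = log(var(Wᵀ E)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datasets import EpochedDataset, Trial
from .exceptions import DimensionError, ParameterError

__all__ = [
    "SpatialFilterBank",
    "learn_csp",
    "learn_csp_ovr",
    "apply_spatial_filter",
    "csp_features",
    "VARIANCE_FLOOR",
]

VARIANCE_FLOOR = 1e-12


@dataclass
class SpatialFilterBank:
    """CSP projection matrix and its provenance.

    ``W`` has shape (n_channels, 2m): columns 0..m-1 are the filters with the
    largest eigenvalues (max variance for ``positive_class``), columns m..2m-1
    those with the smallest.  ``W_full`` is the complete eigenbasis, satisfying
    ``W_fullᵀ (C̄₁+C̄₂) W_full = I``.
    """

    W: np.ndarray
    eigenvalues: np.ndarray
    positive_class: str
    m_pairs: int
    W_full: np.ndarray = field(repr=False, default=None)
    eigenvalues_full: np.ndarray = field(repr=False, default=None)

    @property
    def n_channels(self) -> int:
        return self.W.shape[0]

    @property
    def n_filters(self) -> int:
        return self.W.shape[1]


def _trial_covariances(data: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance per trial, shape (n, c, c)."""
    cov = np.einsum("ncs,nds->ncd", data, data)
    tr = np.trace(cov, axis1=1, axis2=2)
    return cov / tr[:, None, None]


def _fix_signs(W: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def learn_csp(dataset: EpochedDataset, m_pairs: int = 3) -> SpatialFilterBank:
    """Learn CSP spatial filters from a two-class dataset.

    Parameters
    ----------
    dataset : EpochedDataset
        Exactly two classes, each with at least 2 trials.
    m_pairs : int
        Number of filter pairs m; the bank holds 2m filters.

    Returns
    -------
    SpatialFilterBank
        ``positive_class`` is the first class in sorted label order; its
        eigenvalues are the λ of the generalized eigenproblem above.
    """
    classes = dataset.classes
    if len(classes) != 2:
        raise ParameterError(f"CSP needs exactly 2 classes, got {classes}")
    if dataset.n_channels < 2 * m_pairs:
        raise ParameterError(
            f"{dataset.n_channels} channels cannot support {2 * m_pairs} filters"
        )
    covs = _trial_covariances(dataset.data)
    labels = np.array([str(l) for l in dataset.labels])
    mean_covs = []
    for c in classes:
        mask = labels == c
        if mask.sum() < 2:
            raise ParameterError(f"class {c!r} has fewer than 2 trials")
        mean_covs.append(covs[mask].mean(axis=0))
    c1, c2 = mean_covs
    composite = c1 + c2
    # common-average-referenced data has a null common-mode direction, which
    # the generalized eigensolver reports as (near-)singularity
    if np.linalg.cond(composite) > 1e10:
        reg = 1e-9 * np.trace(composite) / composite.shape[0]
        warnings.warn(
            f"singular composite covariance; regularizing diagonal by {reg:.3e}",
            RuntimeWarning,
            stacklevel=2,
        )
        composite = composite + reg * np.eye(composite.shape[0])
    try:
        eigvals, eigvecs = scipy.linalg.eigh(c1, composite)
    except scipy.linalg.LinAlgError:
        reg = 1e-9 * np.trace(composite) / composite.shape[0]
        composite = composite + reg * np.eye(composite.shape[0])
        eigvals, eigvecs = scipy.linalg.eigh(c1, composite)

    eigvals = np.clip(eigvals, 0.0, 1.0)  # numerical dust on degenerate directions
    order = np.argsort(-eigvals, kind="stable")  # descending, ties by index
    eigvals, eigvecs = eigvals[order], _fix_signs(eigvecs[:, order])
    keep = np.r_[np.arange(m_pairs), np.arange(len(eigvals) - m_pairs, len(eigvals))]
    return SpatialFilterBank(
        W=eigvecs[:, keep],
        eigenvalues=eigvals[keep],
        positive_class=classes[0],
        m_pairs=m_pairs,
        W_full=eigvecs,
        eigenvalues_full=eigvals,
    )


def learn_csp_ovr(
    dataset: EpochedDataset, target_class: str, m_pairs: int = 3
) -> SpatialFilterBank:
    """One-vs-rest CSP: ``target_class`` against all remaining trials pooled."""
    labels = {str(l) for l in dataset.labels}
    if target_class not in labels:
        raise ParameterError(f"target class {target_class!r} not in dataset {sorted(labels)}")
    rest_name = "rest~" + target_class  # sorts after any plain label collision risk
    mapping = {l: (l if l == target_class else rest_name) for l in labels}
    binary = dataset.relabel(mapping)
    bank = learn_csp(binary, m_pairs=m_pairs)
    # make the target class the bank's positive class regardless of sort order
    if bank.positive_class != target_class:
        m = m_pairs
        flip = np.r_[np.arange(2 * m - 1, 2 * m - m - 1, -1), np.arange(m - 1, -1, -1)]
        bank = SpatialFilterBank(
            W=bank.W[:, flip],
            eigenvalues=1.0 - bank.eigenvalues[flip],
            positive_class=target_class,
            m_pairs=m_pairs,
            W_full=bank.W_full[:, ::-1],
            eigenvalues_full=(1.0 - bank.eigenvalues_full)[::-1],
        )
    return bank


def apply_spatial_filter(bank: SpatialFilterBank, trial: Trial) -> np.ndarray:
    """Spatially filtered signal Z = Wᵀ E, shape (2m, n_samples)."""
    if trial.n_channels != bank.n_channels:
        raise DimensionError(
            f"trial has {trial.n_channels} channels, filter bank expects {bank.n_channels}"
        )
    return bank.W.T @ trial.data


def csp_features(Z: np.ndarray) -> np.ndarray:
    """Log-variance feature vector y with yᵢ = log(var(Zᵢ)).

    Sample variance (divisor n−1) per row; variances below
    ``VARIANCE_FLOOR`` are floored with a warning so the log stays finite.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] < 2:
        raise ParameterError("need at least 2 samples per filtered row")
    v = Z.var(axis=1, ddof=1)
    if np.any(v < VARIANCE_FLOOR):
        warnings.warn(
            "variance below floor; clamping before log", RuntimeWarning, stacklevel=2
        )
        v = np.maximum(v, VARIANCE_FLOOR)
    return np.log(v)
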