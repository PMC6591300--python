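"""Fisher linear discriminant projection to one dimension.

The whole-trial CSP log-variance vector (d = 2m = 6) is reduced to a single
scalar with the classical Fisher direction w ∝ Sw⁻¹(μ₁ − μ₂), where Sw is the
pooled within-class scatter.  The projection is centered between the class
means, so thresholding at 0 reproduces the equal-prior LDA decision rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateSeparationError, DimensionError, ParameterError

__all__ = ["LdaProjection", "fit_lda", "project_lda"]

_COND_LIMIT = 1e8


@dataclass
class LdaProjection:
    """Unit-norm Fisher direction ``w``, centering offset ``b`` and the
    projected class means (class order = sorted labels)."""

    w: np.ndarray
    b: float
    class_means_projected: tuple[float, float]
    classes: tuple[str, str]


def fit_lda(features: np.ndarray, labels) -> LdaProjection:
    """Fit the Fisher direction on an n x d feature matrix with 2 classes.

    The sign of ``w`` is fixed so the first class (sorted label order)
    projects higher.  When Sw is ill-conditioned (condition number above
    1e8) it is shrunk toward its diagonal for numerical stability.

    Raises
    ------
    DegenerateSeparationError
        If the class means coincide.
    """
    X = np.asarray(features, dtype=float)
    labels = np.array([str(l) for l in labels])
    if X.ndim != 2 or len(labels) != X.shape[0]:
        raise DimensionError("features must be n x d with one label per row")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ParameterError(f"LDA needs exactly 2 classes, got {classes}")
    mus, scatters, counts = [], [], []
    for c in classes:
        Xc = X[labels == c]
        if Xc.shape[0] < 2:
            raise ParameterError(f"class {c!r} has fewer than 2 samples")
        mu = Xc.mean(axis=0)
        mus.append(mu)
        scatters.append((Xc - mu).T @ (Xc - mu))
        counts.append(Xc.shape[0])
    mu1, mu2 = mus
    diff = mu1 - mu2
    if np.allclose(diff, 0.0):
        raise DegenerateSeparationError("class means coincide; no discriminant direction")
    Sw = (scatters[0] + scatters[1]) / (counts[0] + counts[1] - 2)
    if np.linalg.cond(Sw) > _COND_LIMIT:
        shrink = 0.1
        Sw = (1 - shrink) * Sw + shrink * np.diag(np.diag(Sw))
        if np.linalg.cond(Sw) > _COND_LIMIT:  # diagonal itself near-singular
            Sw = Sw + 1e-12 * np.trace(Sw) / Sw.shape[0] * np.eye(Sw.shape[0])
    w = np.linalg.solve(Sw, diff)
    w = w / np.linalg.norm(w)
    if w @ mu1 < w @ mu2:
        w = -w
    b = -float(w @ (mu1 + mu2) / 2.0)
    return LdaProjection(
        w=w,
        b=b,
        class_means_projected=(float(w @ mu1 + b), float(w @ mu2 + b)),
        classes=(classes[0], classes[1]),
    )


def project_lda(p: LdaProjection, x: np.ndarray) -> float | np.ndarray:
    """Affine projection w·x + b; accepts a d-vector or an n x d matrix."""
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != p.w.shape[0]:
        raise DimensionError(
            f"feature dimension {x.shape[-1]} does not match projection ({p.w.shape[0]})"
        )
    out = x @ p.w + p.b
    return float(out) if out.ndim == 0 else out
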