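"""Bayesian optimization of the LSTM learn rate and L2 penalty.

The two hyper-parameters are searched over the boxes [1e-4, 1e-1] (initial
learn rate) and [1e-5, 1e-3] (L2 regularization), in log10 coordinates since
each spans several decades.  A Gaussian-process surrogate (Matern 5/2) is fit
to the observed objective values and the next point maximizes expected
improvement over a random candidate set.  The objective is a misclassification
rate in [0, 1], by default estimated with stratified 10-fold cross-validation
on the training split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel

from .exceptions import OptimizationFailureError, ParameterError

__all__ = ["HyperBox", "HyperResult", "bayes_optimize"]

_N_INITIAL = 5
_N_CANDIDATES = 2048


@dataclass(frozen=True)
class HyperBox:
    """Search ranges for (initial learn rate, L2 regularization)."""

    learn_rate_range: tuple[float, float] = (1e-4, 1e-1)
    l2_range: tuple[float, float] = (1e-5, 1e-3)
    budget: int = 30
    seed: int = 0

    def validate(self) -> None:
        for lo, hi in (self.learn_rate_range, self.l2_range):
            if not (0 < lo < hi):
                raise ParameterError(f"range must satisfy 0 < lo < hi, got ({lo}, {hi})")
        if self.budget < 5:
            raise ParameterError(f"budget must be >= 5, got {self.budget}")

    @property
    def log_bounds(self) -> np.ndarray:
        return np.log10(
            np.array([self.learn_rate_range, self.l2_range], dtype=float)
        )


@dataclass
class HyperResult:
    """Best observed hyper-parameters and the full evaluation trace."""

    best_learn_rate: float
    best_l2: float
    best_objective: float
    trace: list[tuple[float, float, float]] = field(default_factory=list)
    # trace entries: (learn_rate, l2, objective); NaN objective = failed eval

    def incumbent_curve(self) -> np.ndarray:
        """Running minimum of the observed objective along the trace."""
        vals = np.array([t[2] for t in self.trace])
        vals = np.where(np.isnan(vals), np.inf, vals)
        return np.minimum.accumulate(vals)

    def trace_to_csv(self, path) -> None:
        """Tabular evaluation log: one row per objective evaluation."""
        import pandas as pd

        df = pd.DataFrame(self.trace, columns=["learn_rate", "l2", "objective"])
        df["incumbent"] = self.incumbent_curve()
        df.to_csv(path, index_label="evaluation")


def _expected_improvement(mu, sigma, best):
    sigma = np.maximum(sigma, 1e-12)
    z = (best - mu) / sigma
    return (best - mu) * norm.cdf(z) + sigma * norm.pdf(z)


def bayes_optimize(objective, box: HyperBox = HyperBox()) -> HyperResult:
    """Minimize ``objective(learn_rate, l2)`` over the box by GP-EI search.

    The first 5 evaluations are seeded uniform draws in log10 space; each
    remaining evaluation maximizes expected improvement of a Matern-5/2 GP
    over a fresh random candidate set.  Evaluations that raise are recorded
    as NaN in the trace and excluded from the surrogate.  Deterministic for a
    fixed ``box.seed``.

    Returns
    -------
    HyperResult
        Incumbent (lowest observed objective) and the trace of all
        ``budget`` evaluations.
    """
    box.validate()
    rng = np.random.default_rng(box.seed)
    bounds = box.log_bounds  # (2, 2): rows = params, cols = (lo, hi)
    span = bounds[:, 1] - bounds[:, 0]

    X_log: list[np.ndarray] = []
    y_obs: list[float] = []
    trace: list[tuple[float, float, float]] = []

    def evaluate(pt_log: np.ndarray) -> None:
        lr, l2 = 10.0 ** pt_log
        try:
            val = float(objective(lr, l2))
        except Exception:
            trace.append((lr, l2, float("nan")))
            return
        X_log.append(pt_log)
        y_obs.append(val)
        trace.append((lr, l2, val))

    for _ in range(_N_INITIAL):
        evaluate(bounds[:, 0] + span * rng.random(2))

    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * Matern(
        length_scale=[1.0, 1.0], length_scale_bounds=(1e-2, 1e2), nu=2.5
    ) + WhiteKernel(1e-6, (1e-10, 1e-1))
    for _ in range(box.budget - _N_INITIAL):
        if not y_obs:
            evaluate(bounds[:, 0] + span * rng.random(2))
            continue
        X = np.array(X_log)
        y = np.array(y_obs)
        gp = GaussianProcessRegressor(
            kernel=kernel, normalize_y=True, random_state=int(rng.integers(2**31))
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # GP convergence chatter on tiny data
            gp.fit(X, y)
            cand = bounds[:, 0] + span * rng.random((_N_CANDIDATES, 2))
            mu, sigma = gp.predict(cand, return_std=True)
        ei = _expected_improvement(mu, sigma, y.min())
        evaluate(cand[int(np.argmax(ei))])

    if not y_obs:
        raise OptimizationFailureError("every hyper-parameter evaluation failed")
    best = int(np.argmin(y_obs))
    lr, l2 = 10.0 ** X_log[best]
    return HyperResult(
        best_learn_rate=float(lr),
        best_l2=float(l2),
        best_objective=float(y_obs[best]),
        trace=trace,
    )
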