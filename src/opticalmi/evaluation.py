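"""Cross-validated evaluation: misclassification, sensitivity, specificity,
Cohen's kappa, the 10x10-fold harness, and the paired t-test.

The 10x10-fold scheme repeats stratified 10-fold cross-validation ten times
with independent seeded partitions; each trial is tested exactly once per
repetition and all model fitting happens inside the training folds.  Fold
scores are averaged (not count-pooled) into the aggregate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from sklearn.model_selection import StratifiedKFold

from .datasets import EpochedDataset
from .exceptions import ParameterError

__all__ = [
    "ConfusionCounts",
    "PerformanceReport",
    "compute_metrics",
    "confusion_from_predictions",
    "cross_validate",
    "paired_ttest",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts; the positive class is fixed by convention."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ParameterError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def compute_metrics(c: ConfusionCounts):
    """Misclassification, sensitivity, specificity and Cohen's kappa.

    misclassification = (FP+FN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), kappa = (p_a − p_e)/(1 − p_e) with
    p_a = (TP+TN)/total and p_e from the marginal products.  A metric whose
    margin is empty is returned as NaN; the others are still computed.
    """
    n = c.total
    if n == 0:
        raise ParameterError("cannot compute metrics on zero trials")
    miscl = (c.FP + c.FN) / n
    pos = c.TP + c.FN
    neg = c.TN + c.FP
    sens = c.TP / pos if pos else float("nan")
    spec = c.TN / neg if neg else float("nan")
    p_a = (c.TP + c.TN) / n
    p_e = ((c.TP + c.FN) * (c.TP + c.FP) + (c.TN + c.FP) * (c.TN + c.FN)) / n**2
    kappa = (p_a - p_e) / (1 - p_e) if p_e < 1 else float("nan")
    return miscl, sens, spec, kappa


def confusion_from_predictions(true, pred, positive_class) -> ConfusionCounts:
    true = np.array([str(x) for x in true])
    pred = np.array([str(x) for x in pred])
    pos = str(positive_class)
    return ConfusionCounts(
        TP=int(np.sum((true == pos) & (pred == pos))),
        TN=int(np.sum((true != pos) & (pred != pos))),
        FP=int(np.sum((true != pos) & (pred == pos))),
        FN=int(np.sum((true == pos) & (pred != pos))),
    )


@dataclass
class PerformanceReport:
    """Per-fold scores and their fold-averaged aggregate."""

    per_fold: pd.DataFrame  # repetition, fold, misclassification, sensitivity,
    # specificity, kappa
    positive_class: str
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def aggregate(self) -> pd.Series:
        cols = ["misclassification", "sensitivity", "specificity", "kappa"]
        return self.per_fold[cols].mean()

    @property
    def aggregate_sd(self) -> pd.Series:
        cols = ["misclassification", "sensitivity", "specificity", "kappa"]
        return self.per_fold[cols].std(ddof=1)

    def summary(self) -> str:
        agg, sd = self.aggregate, self.aggregate_sd
        lines = [
            "Cross-validated performance",
            "===========================",
            f"folds evaluated      : {len(self.per_fold)}",
            f"positive class       : {self.positive_class}",
        ]
        for name in ["misclassification", "sensitivity", "specificity", "kappa"]:
            lines.append(f"{name:<21}: {agg[name]:.4f} +/- {sd[name]:.4f}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        with open(path, "w") as f:
            f.write(f"# positive_class={self.positive_class} seed={self.seed}\n")
            full = self.per_fold.copy()
            agg = self.aggregate
            agg_row = {"repetition": "aggregate", "fold": ""}
            agg_row.update({k: agg[k] for k in agg.index})
            full = pd.concat([full, pd.DataFrame([agg_row])], ignore_index=True)
            full.to_csv(f, index=False)


def cross_validate(
    data: EpochedDataset,
    trainer,
    k: int = 10,
    reps: int = 10,
    seed: int = 0,
    positive_class: str | None = None,
) -> PerformanceReport:
    """Repeated stratified k-fold cross-validation of a training procedure.

    Parameters
    ----------
    data : EpochedDataset
    trainer : callable
        ``trainer(train_dataset, seed) -> predict`` where ``predict`` maps an
        :class:`EpochedDataset` to an array of labels.  All fitting must
        happen inside ``trainer``.
    k, reps : int
        Folds per repetition and number of repetitions (default 10 x 10).
    seed : int
        Master seed; repetition r partitions with ``seed + r`` and the
        trainer receives a per-fold derived seed.
    positive_class : str, optional
        Class treated as positive in the binary metrics (default: first
        class in sorted order).

    Returns
    -------
    PerformanceReport
        One row per (repetition, fold); aggregate = mean over fold scores.
    """
    labels = np.array([str(l) for l in data.labels])
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ParameterError(
            f"stratified {k}-fold needs >= {k} trials per class; "
            f"smallest class has {counts.min()}"
        )
    if positive_class is None:
        positive_class = sorted(classes)[0]
    rows = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            fold_seed = (seed + 9973 * rep + 131 * fold) % (2**31)
            predict = trainer(data.subset(tr_idx), fold_seed)
            pred = predict(data.subset(te_idx))
            conf = confusion_from_predictions(labels[te_idx], pred, positive_class)
            miscl, sens, spec, kappa = compute_metrics(conf)
            rows.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    "misclassification": miscl,
                    "sensitivity": sens,
                    "specificity": spec,
                    "kappa": kappa,
                }
            )
    return PerformanceReport(pd.DataFrame(rows), positive_class=positive_class, seed=seed)


def paired_ttest(rates_a, rates_b):
    """Classical paired t-test between per-subject rates of two methods.

    Returns ``(t, p)`` with a two-sided p-value from the t distribution with
    n−1 degrees of freedom.  Raises on all-equal differences (zero variance).
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ParameterError("need two equal-length 1-D arrays with >= 2 entries")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ParameterError("differences have zero variance; t statistic undefined")
    n = len(d)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * t_dist.sf(abs(t), df=n - 1)
    return float(t), float(p)
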