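"""Two-stage one-vs-rest cascade for 3-class real-time-style operation.

Stage 1 separates non-task signals (blinks, eye movement, rest) from pooled
motor-imagery trials; trials called MI go on to stage 2, which separates left
from right hand.  Each stage is a full fused predictor with its own spatial
filters.  Non-task trials are randomly subsampled to match the total MI
count before stage-1 training, so neither class dominates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .datasets import EpochedDataset, Trial
from .exceptions import ParameterError
from .pipeline import OpticalModel, OpticalResults

__all__ = [
    "CascadeModel",
    "balance_non_task",
    "train_cascade",
    "predict_cascade",
    "cross_validate_cascade",
]

_MI_POOL_LABEL = "mi-task"


@dataclass
class CascadeModel:
    """Trained two-stage cascade: stage 1 non-task vs MI, stage 2 left vs right."""

    stage1: OpticalResults
    stage2: OpticalResults
    labels: tuple[str, str, str]  # (mi class 1, mi class 2, non-task)
    nontask_label: str


def balance_non_task(
    mi: EpochedDataset, nontask: EpochedDataset, seed: int = 0
) -> EpochedDataset:
    """Random non-task subsample of size equal to the total MI trial count.

    If fewer non-task trials exist than MI trials, all are kept with a
    warning.
    """
    if len(mi) == 0 or len(nontask) == 0:
        raise ParameterError("both MI and non-task datasets must be non-empty")
    n = len(mi)
    if len(nontask) < n:
        warnings.warn(
            f"only {len(nontask)} non-task trials for {n} MI trials; keeping all",
            RuntimeWarning,
            stacklevel=2,
        )
        return nontask.subset(np.arange(len(nontask)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(nontask), size=n, replace=False)
    return nontask.subset(np.sort(idx))


def train_cascade(
    mi: EpochedDataset,
    nontask: EpochedDataset,
    seed: int = 0,
    **model_kwargs,
) -> CascadeModel:
    """Train both cascade stages.

    Stage 1 trains on the balanced non-task subsample against all MI trials
    pooled under one label; stage 2 trains on the two MI classes only and
    never sees a non-task trial.
    """
    mi_classes = mi.classes
    if len(mi_classes) != 2:
        raise ParameterError(f"MI dataset must have 2 classes, got {mi_classes}")
    nt_classes = nontask.classes
    if len(nt_classes) != 1:
        raise ParameterError(f"non-task dataset must have 1 class, got {nt_classes}")
    nontask_label = nt_classes[0]

    balanced_nt = balance_non_task(mi, nontask, seed=seed)
    pooled_mi = mi.relabel({c: _MI_POOL_LABEL for c in mi_classes})
    stage1_data = EpochedDataset.concatenate([pooled_mi, balanced_nt])
    stage1 = OpticalModel(stage1_data, **model_kwargs).fit(seed=seed)
    stage2 = OpticalModel(mi, **model_kwargs).fit(seed=seed + 1)
    return CascadeModel(
        stage1=stage1,
        stage2=stage2,
        labels=(mi_classes[0], mi_classes[1], nontask_label),
        nontask_label=nontask_label,
    )


def predict_cascade(model: CascadeModel, trial: Trial) -> str:
    """3-class label: stage 1 gates non-task, stage 2 resolves left vs right."""
    if model.stage1.predict(trial) == model.nontask_label:
        return model.nontask_label
    return model.stage2.predict(trial)


def _predict_cascade_dataset(model: CascadeModel, dataset: EpochedDataset) -> np.ndarray:
    s1 = model.stage1.predict_dataset(dataset)
    out = np.array(s1, dtype=object)
    mi_idx = np.where(s1 != model.nontask_label)[0]
    if len(mi_idx):
        out[mi_idx] = model.stage2.predict_dataset(dataset.subset(mi_idx))
    return out


def cross_validate_cascade(
    mi: EpochedDataset,
    nontask: EpochedDataset,
    k: int = 10,
    reps: int = 1,
    seed: int = 0,
    **model_kwargs,
):
    """Stratified k-fold CV of the full 3-class cascade.

    The non-task balancing subsample is re-drawn each repetition with the
    repetition's seed.  Returns a DataFrame with one row per (repetition,
    fold): 3-class misclassification and the confusion entries.
    """
    data = EpochedDataset.concatenate([mi, nontask])
    labels = np.array([str(l) for l in data.labels])
    nontask_label = nontask.classes[0]
    rows = []
    for rep in range(reps):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (tr_idx, te_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            train = data.subset(tr_idx)
            fold_seed = (seed + 9973 * rep + 131 * fold) % (2**31)
            model = train_cascade(
                train.select_classes([c for c in train.classes if c != nontask_label]),
                train.select_classes([nontask_label]),
                seed=fold_seed,
                **model_kwargs,
            )
            pred = _predict_cascade_dataset(model, data.subset(te_idx))
            true = labels[te_idx]
            rows.append(
                {
                    "repetition": rep,
                    "fold": fold,
                    "misclassification": float(np.mean(pred != true)),
                    "n_test": len(te_idx),
                }
            )
    return pd.DataFrame(rows)
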