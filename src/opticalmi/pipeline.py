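"""The fused CSP + LSTM predictor.

:class:`OpticalModel` is built from a preprocessed two-class
:class:`~opticalmi.datasets.EpochedDataset`; :meth:`OpticalModel.fit` returns
an :class:`OpticalResults` holding every trained stage:

* a whole-trial CSP bank whose 2m log-variance features are reduced to one
  scalar by Fisher LDA;
* a segment-level CSP bank learned on the pooled sliding windows of the
  training trials, feeding per-trial sequence feature matrices to a
  regression LSTM whose output is the second scalar;
* a z-score standardization of the two scalars and an RBF-kernel SVM fused
  on top.

Hyper-parameters of the LSTM (initial learn rate, L2) can be chosen by
Gaussian-process Bayesian optimization with inner cross-validation on the
training split (``optimize=True``); otherwise the defaults (1e-2, 1e-4) are
used — the unoptimized variant.

Ablation modes ``"csp_lda"`` and ``"lstm"`` run the pipeline on a single
feature to quantify what the fusion adds.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace

import numpy as np
from sklearn.svm import SVC

from .csp import SpatialFilterBank, apply_spatial_filter, csp_features, learn_csp
from .datasets import EpochedDataset, Trial
from .exceptions import DimensionError, ParameterError
from .hyperopt import HyperBox, HyperResult, bayes_optimize
from .lda import LdaProjection, fit_lda, project_lda
from .lstm import LstmConfig, LstmRegressor, train_lstm_regressor, _forward_batch
from .preprocessing import BandpassSpec
from .segmentation import WindowParams, build_sequence_features, default_window_params

__all__ = [
    "OpticalModel",
    "OpticalResults",
    "BivariateFeature",
    "train_optical",
    "make_trainer",
    "load_results",
]

_MODES = ("fused", "csp_lda", "lstm")


@dataclass(frozen=True)
class BivariateFeature:
    """The two standardized scalars fed to the SVM."""

    f_lda: float
    f_lstm: float


@dataclass
class _SvmParams:
    """RBF-kernel decision function extracted from a fitted SVC."""

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    gamma: float
    classes: tuple[str, str]
    tie_class: str

    def decision(self, X: np.ndarray) -> np.ndarray:
        d2 = ((X[:, None, :] - self.support_vectors[None, :, :]) ** 2).sum(axis=2)
        return (self.dual_coef * np.exp(-self.gamma * d2)).sum(axis=1) + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        df = self.decision(X)
        out = np.where(df > 0, self.classes[1], self.classes[0]).astype(object)
        out[df == 0] = self.tie_class
        return out


class OpticalModel:
    """Fused CSP + LSTM predictor over a preprocessed two-class dataset.

    Parameters
    ----------
    dataset : EpochedDataset
        Training trials, already epoched, referenced and band-pass filtered
        (see :mod:`opticalmi.preprocessing`).
    window_params : WindowParams, optional
        Sliding-window geometry; default 25% length / 5% overlap of the
        trial length.
    lstm_config : LstmConfig, optional
        Network and optimizer settings (defaults: 100+20 hidden units, learn
        rate 1e-2, L2 1e-4, 100 epochs).
    hyper_box : HyperBox, optional
        Search ranges and budget for Bayesian optimization.
    mode : {"fused", "csp_lda", "lstm"}
        Which features the SVM sees.
    m_pairs : int
        CSP filter pairs per bank (2m filters; default 3).
    bandpass : BandpassSpec
        Recorded for provenance with the trained model.
    """

    def __init__(
        self,
        dataset: EpochedDataset,
        window_params: WindowParams | None = None,
        lstm_config: LstmConfig | None = None,
        hyper_box: HyperBox | None = None,
        mode: str = "fused",
        m_pairs: int = 3,
        bandpass: BandpassSpec = BandpassSpec(),
    ) -> None:
        if mode not in _MODES:
            raise ParameterError(f"mode must be one of {_MODES}, got {mode!r}")
        if len(dataset.classes) != 2:
            raise ParameterError(
                f"OPTICAL is a two-class predictor; dataset has classes {dataset.classes}"
            )
        self.dataset = dataset
        self.window_params = window_params or default_window_params(dataset.n_samples)
        self.lstm_config = lstm_config or LstmConfig()
        self.hyper_box = hyper_box or HyperBox()
        self.mode = mode
        self.m_pairs = m_pairs
        self.bandpass = bandpass

    # -- training ----------------------------------------------------------
    def fit(
        self,
        optimize: bool = False,
        seed: int = 0,
        hyper_objective: str = "full",
        inner_k: int = 10,
    ) -> "OpticalResults":
        """Train every stage on the model's dataset.

        Parameters
        ----------
        optimize : bool
            Select the LSTM learn rate and L2 by Bayesian optimization with
            ``inner_k``-fold CV on the training split.  Off by default (the
            unoptimized variant with the toolchain default rates).
        seed : int
            Seeds LSTM initialization/shuffling and the optimizer.
        hyper_objective : {"full", "lstm"}
            Optimize the deployed fused pipeline's CV misclassification, or
            a cheaper LSTM-only surrogate.
        """
        data = self.dataset
        classes = data.classes

        csp_trial = learn_csp(data, m_pairs=self.m_pairs)
        X_trial = np.vstack(
            [csp_features(apply_spatial_filter(csp_trial, tr)) for tr in data.trials()]
        )
        lda = fit_lda(X_trial, data.labels) if self.mode != "lstm" else None

        csp_seg, sequences = self._segment_path(data)

        hyper: HyperResult | None = None
        lstm_cfg = replace(self.lstm_config, init_seed=seed)
        lstm = None
        if self.mode != "csp_lda":
            if optimize:
                hyper = self._optimize_hyper(seed, hyper_objective, inner_k)
                lstm_cfg = replace(
                    lstm_cfg,
                    initial_learn_rate=hyper.best_learn_rate,
                    l2_regularization=hyper.best_l2,
                )
            lstm = train_lstm_regressor(sequences, data.labels, lstm_cfg)

        feats = self._raw_features(
            lda, lstm, X_trial=X_trial, sequences=sequences
        )
        mean = feats.mean(axis=0)
        scale = feats.std(axis=0)
        scale[scale < 1e-12] = 1.0
        Z = (feats - mean) / scale

        labels = np.array([str(l) for l in data.labels])
        d = Z.shape[1]
        gamma = 1.0 / (2.0 * d * max(Z.var(axis=0).mean(), 1e-12))
        svc = SVC(C=1.0, kernel="rbf", gamma=gamma)
        svc.fit(Z, labels)
        counts = {c: int(np.sum(labels == c)) for c in classes}
        tie_class = max(classes, key=lambda c: (counts[c], -classes.index(c)))
        svm = _SvmParams(
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
            gamma=float(gamma),
            classes=(str(svc.classes_[0]), str(svc.classes_[1])),
            tie_class=tie_class,
        )
        res = OpticalResults(
            model=self,
            classes=(classes[0], classes[1]),
            mode=self.mode,
            bandpass=self.bandpass,
            window_params=self.window_params,
            csp_trial=csp_trial,
            csp_segment=csp_seg,
            lda=lda,
            lstm=lstm,
            lstm_config=lstm_cfg,
            svm=svm,
            feature_mean=mean,
            feature_scale=scale,
            hyper=hyper,
            seed=seed,
        )
        res.training_misclassification = float(
            np.mean(res.predict_dataset(data) != labels)
        )
        return res

    # -- internals ----------------------------------------------------------
    def _segment_path(self, data: EpochedDataset):
        """Learn the segment CSP bank on pooled training windows, then build
        per-trial sequence feature matrices."""
        from .segmentation import segment_trial

        seg_data, seg_labels = [], []
        for tr in data.trials():
            for w in segment_trial(tr, self.window_params):
                seg_data.append(w)
                seg_labels.append(tr.label)
        segments = EpochedDataset(
            np.stack(seg_data), np.array(seg_labels, dtype=object), data.fs
        )
        csp_seg = learn_csp(segments, m_pairs=self.m_pairs)
        sequences = [
            build_sequence_features(tr, self.window_params, csp_seg)
            for tr in data.trials()
        ]
        return csp_seg, sequences

    def _optimize_hyper(self, seed: int, objective: str, inner_k: int) -> HyperResult:
        from sklearn.model_selection import StratifiedKFold

        data = self.dataset
        labels = np.array([str(l) for l in data.labels])
        box = replace(self.hyper_box, seed=seed)
        skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
        splits = list(skf.split(np.zeros(len(labels)), labels))

        if objective == "lstm":
            _, sequences = self._segment_path(data)
            seqs = np.stack(sequences)

            def score(lr, l2):
                errs = []
                for f, (tr, te) in enumerate(splits):
                    cfg = replace(
                        self.lstm_config,
                        initial_learn_rate=lr,
                        l2_regularization=l2,
                        init_seed=seed + f,
                    )
                    net = train_lstm_regressor(
                        [seqs[i] for i in tr], labels[tr], cfg
                    )
                    out = _forward_batch(net, seqs[te], want_cache=False)
                    cls = sorted(set(labels))
                    pred = np.where(out > 0, cls[1], cls[0])
                    errs.append(np.mean(pred != labels[te]))
                return float(np.mean(errs))

        elif objective == "full":

            def score(lr, l2):
                errs = []
                for f, (tr, te) in enumerate(splits):
                    cfg = replace(
                        self.lstm_config, initial_learn_rate=lr, l2_regularization=l2
                    )
                    sub = OpticalModel(
                        data.subset(tr),
                        window_params=self.window_params,
                        lstm_config=cfg,
                        mode=self.mode,
                        m_pairs=self.m_pairs,
                        bandpass=self.bandpass,
                    ).fit(optimize=False, seed=seed + f)
                    pred = sub.predict_dataset(data.subset(te))
                    errs.append(np.mean(pred != labels[te]))
                return float(np.mean(errs))

        else:
            raise ParameterError(f"unknown hyper objective {objective!r}")
        return bayes_optimize(score, box)

    def _raw_features(self, lda, lstm, X_trial, sequences) -> np.ndarray:
        cols = []
        if self.mode != "lstm":
            cols.append(np.asarray(project_lda(lda, X_trial), dtype=float))
        if self.mode != "csp_lda":
            out = _forward_batch(lstm, np.stack(sequences), want_cache=False)
            cols.append(np.asarray(out, dtype=float))
        return np.column_stack(cols)


@dataclass
class OpticalResults:
    """A trained predictor: frozen stages, diagnostics and prediction.

    Produced by :meth:`OpticalModel.fit`; every attribute is a function of
    the training split only.
    """

    model: OpticalModel | None
    classes: tuple[str, str]
    mode: str
    bandpass: BandpassSpec
    window_params: WindowParams
    csp_trial: SpatialFilterBank
    csp_segment: SpatialFilterBank
    lda: LdaProjection | None
    lstm: LstmRegressor | None
    lstm_config: LstmConfig
    svm: _SvmParams
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    hyper: HyperResult | None = None
    seed: int = 0
    training_misclassification: float | None = None

    # -- feature extraction -------------------------------------------------
    def _features(self, dataset: EpochedDataset) -> np.ndarray:
        if dataset.n_channels != self.csp_trial.n_channels:
            raise DimensionError(
                f"dataset has {dataset.n_channels} channels, model expects "
                f"{self.csp_trial.n_channels}"
            )
        cols = []
        if self.mode != "lstm":
            X = np.vstack(
                [
                    csp_features(apply_spatial_filter(self.csp_trial, tr))
                    for tr in dataset.trials()
                ]
            )
            cols.append(np.asarray(project_lda(self.lda, X), dtype=float))
        if self.mode != "csp_lda":
            seqs = np.stack(
                [
                    build_sequence_features(tr, self.window_params, self.csp_segment)
                    for tr in dataset.trials()
                ]
            )
            cols.append(
                np.asarray(_forward_batch(self.lstm, seqs, want_cache=False), dtype=float)
            )
        feats = np.column_stack(cols)
        return (feats - self.feature_mean) / self.feature_scale

    def extract_bivariate(self, trial: Trial) -> BivariateFeature:
        """Both standardized scalars for one trial (fused mode only)."""
        if self.mode != "fused":
            raise ParameterError("bivariate features exist only in fused mode")
        ds = EpochedDataset(trial.data[None], np.array([trial.label], dtype=object), trial.fs)
        f = self._features(ds)[0]
        return BivariateFeature(f_lda=float(f[0]), f_lstm=float(f[1]))

    # -- prediction ----------------------------------------------------------
    def predict(self, trial: Trial) -> str:
        """Predicted class label of one trial."""
        ds = EpochedDataset(trial.data[None], np.array([trial.label], dtype=object), trial.fs)
        return str(self.predict_dataset(ds)[0])

    def predict_dataset(self, dataset: EpochedDataset) -> np.ndarray:
        """Predicted labels for every trial of a dataset."""
        return self.svm.predict(self._features(dataset))

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            "OPTICAL predictor (trained)",
            "===========================",
            f"mode                  : {self.mode}",
            f"classes               : {self.classes[0]} vs {self.classes[1]}",
            f"band-pass             : {self.bandpass.low}-{self.bandpass.high} Hz "
            f"(order {self.bandpass.order}, zero-phase={self.bandpass.zero_phase})",
            f"window params (l,t,S) : ({self.window_params.l}, "
            f"{self.window_params.t}, {self.window_params.S})",
            f"CSP filters per bank  : {self.csp_trial.n_filters}",
            f"trial-CSP eigenvalues : "
            + ", ".join(f"{v:.3f}" for v in self.csp_trial.eigenvalues),
        ]
        if self.lstm is not None:
            lines += [
                f"LSTM hidden units     : {self.lstm_config.hidden_units}",
                f"LSTM learn rate / L2  : {self.lstm_config.initial_learn_rate:.3g} / "
                f"{self.lstm_config.l2_regularization:.3g}"
                + ("  (Bayesian-optimized)" if self.hyper is not None else "  (defaults)"),
                f"LSTM final train MSE  : {self.lstm.training_curve[-1]:.4f}",
            ]
        if self.training_misclassification is not None:
            lines.append(
                f"training misclass.    : {self.training_misclassification:.4f}"
            )
        return "\n".join(lines)

    # -- serialization --------------------------------------------------------
    def save(self, path) -> None:
        """Write the trained model to a single ``.npz`` container."""
        meta = {
            "classes": list(self.classes),
            "mode": self.mode,
            "bandpass": asdict(self.bandpass),
            "window_params": asdict(self.window_params),
            "lstm_config": {
                **asdict(self.lstm_config),
                "hidden_units": list(self.lstm_config.hidden_units),
            },
            "csp_trial_positive": self.csp_trial.positive_class,
            "csp_trial_m": self.csp_trial.m_pairs,
            "csp_segment_positive": self.csp_segment.positive_class,
            "csp_segment_m": self.csp_segment.m_pairs,
            "svm_classes": list(self.svm.classes),
            "svm_tie_class": self.svm.tie_class,
            "svm_intercept": self.svm.intercept,
            "svm_gamma": self.svm.gamma,
            "lda_b": None if self.lda is None else self.lda.b,
            "lda_classes": None if self.lda is None else list(self.lda.classes),
            "lda_means": None if self.lda is None else list(self.lda.class_means_projected),
            "seed": self.seed,
            "training_misclassification": self.training_misclassification,
            "has_lstm": self.lstm is not None,
        }
        arrays = {
            "meta_json": np.frombuffer(
                json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
            ),
            "csp_trial_W": self.csp_trial.W,
            "csp_trial_eig": self.csp_trial.eigenvalues,
            "csp_seg_W": self.csp_segment.W,
            "csp_seg_eig": self.csp_segment.eigenvalues,
            "feature_mean": self.feature_mean,
            "feature_scale": self.feature_scale,
            "svm_sv": self.svm.support_vectors,
            "svm_dual": self.svm.dual_coef,
        }
        if self.lda is not None:
            arrays["lda_w"] = self.lda.w
        if self.lstm is not None:
            for k, v in self.lstm.params.items():
                arrays[f"lstm_{k}"] = v
            arrays["lstm_curve"] = np.asarray(self.lstm.training_curve)
        np.savez(path, **arrays)


def load_results(path) -> OpticalResults:
    """Reload a model saved by :meth:`OpticalResults.save`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode())
        csp_trial = SpatialFilterBank(
            W=z["csp_trial_W"],
            eigenvalues=z["csp_trial_eig"],
            positive_class=meta["csp_trial_positive"],
            m_pairs=meta["csp_trial_m"],
        )
        csp_seg = SpatialFilterBank(
            W=z["csp_seg_W"],
            eigenvalues=z["csp_seg_eig"],
            positive_class=meta["csp_segment_positive"],
            m_pairs=meta["csp_segment_m"],
        )
        lda = None
        if "lda_w" in z.files:
            lda = LdaProjection(
                w=z["lda_w"],
                b=meta["lda_b"],
                class_means_projected=tuple(meta["lda_means"]),
                classes=tuple(meta["lda_classes"]),
            )
        cfg_d = dict(meta["lstm_config"])
        cfg_d["hidden_units"] = tuple(cfg_d["hidden_units"])
        lstm_cfg = LstmConfig(**cfg_d)
        lstm = None
        if meta["has_lstm"]:
            params = {
                k[len("lstm_") :]: z[k]
                for k in z.files
                if k.startswith("lstm_") and k != "lstm_curve"
            }
            lstm = LstmRegressor(
                params=params,
                config=lstm_cfg,
                training_curve=[float(v) for v in z["lstm_curve"]],
            )
        svm = _SvmParams(
            support_vectors=z["svm_sv"],
            dual_coef=z["svm_dual"],
            intercept=float(meta["svm_intercept"]),
            gamma=float(meta["svm_gamma"]),
            classes=tuple(meta["svm_classes"]),
            tie_class=meta["svm_tie_class"],
        )
        return OpticalResults(
            model=None,
            classes=tuple(meta["classes"]),
            mode=meta["mode"],
            bandpass=BandpassSpec(**meta["bandpass"]),
            window_params=WindowParams(**meta["window_params"]),
            csp_trial=csp_trial,
            csp_segment=csp_seg,
            lda=lda,
            lstm=lstm,
            lstm_config=lstm_cfg,
            svm=svm,
            feature_mean=z["feature_mean"],
            feature_scale=z["feature_scale"],
            seed=int(meta["seed"]),
            training_misclassification=meta["training_misclassification"],
        )


def train_optical(
    dataset: EpochedDataset,
    optimize: bool = False,
    seed: int = 0,
    **model_kwargs,
) -> OpticalResults:
    """Convenience wrapper: build an :class:`OpticalModel` and fit it."""
    return OpticalModel(dataset, **model_kwargs).fit(optimize=optimize, seed=seed)


def make_trainer(optimize: bool = False, **model_kwargs):
    """A ``trainer(dataset, seed) -> predict`` closure for the CV harness."""

    def trainer(train_ds: EpochedDataset, seed: int):
        res = OpticalModel(train_ds, **model_kwargs).fit(optimize=optimize, seed=seed)
        return res.predict_dataset

    return trainer
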