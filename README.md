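# opticalmi

A subject-dependent motor-imagery (MI) EEG decoder for brain-computer
interfaces. It implements the OPTICAL predictor: common spatial patterns
(CSP) fused with an LSTM-derived temporal feature, classified by an
RBF-kernel SVM, with Bayesian optimization of the LSTM hyper-parameters and
a repeated cross-validation harness. A seeded synthetic MI-EEG generator
with known ground truth makes every stage testable without external
recordings.

## The method

Imagined hand movement suppresses mu/beta band power over contralateral
sensorimotor cortex (event-related desynchronization). After epoching
(2 s window, 0.5 s post-cue), common average referencing and a 7–30 Hz
Butterworth band-pass, a trial `E` is described by two scalars:

1. **Spatial**: CSP filters `W` solve `C̄₁ w = λ (C̄₁+C̄₂) w` over the
   class-mean normalized covariances; the whole-trial log-variance features
   `y = log(var(Wᵀ E))` (2m = 6 filters) are reduced to one scalar by a
   Fisher LDA projection.
2. **Temporal**: the trial is cut into N sliding windows (length 25%,
   overlap 5% of the trial), a second CSP bank learned on the pooled
   training windows turns each trial into an N × 6 feature sequence, and a
   two-layer regression LSTM (100 + 20 hidden units, SGD with momentum,
   targets ±1) maps the sequence to one scalar.

The two standardized scalars are fused by an RBF-kernel SVM. The LSTM's
initial learn rate and L2 penalty can be selected by Gaussian-process
Bayesian optimization over [1e-4, 1e-1] × [1e-5, 1e-3] with 10-fold CV on
the training split. For a 3-class real-time-style setting (left / right /
non-task), two predictors are cascaded one-vs-rest: non-task vs MI first,
then left vs right. Performance is reported as misclassification,
sensitivity, specificity and Cohen's kappa under 10×10-fold stratified CV.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import opticalmi as om

cfg = om.SyntheticConfig(n_trials_per_class=60, mixing_seed=7, noise_seed=8)
ds = om.preprocess_dataset(om.generate_mi_dataset(cfg))

res = om.OpticalModel(ds).fit(seed=0)
print(res.summary())

f = res.extract_bivariate(ds[0])
print(f"first trial: true={ds[0].label!r} predicted={res.predict(ds[0])!r} "
      f"f_lda={f.f_lda:+.2f} f_lstm={f.f_lstm:+.2f}")

report = om.cross_validate(ds, om.make_trainer(), k=10, reps=2, seed=0)
print(report.summary())
```

prints

```
OPTICAL predictor (trained)
===========================
mode                  : fused
classes               : left vs right
band-pass             : 7.0-30.0 Hz (order 4, zero-phase=True)
window params (l,t,S) : (50, 10, 200)
CSP filters per bank  : 6
trial-CSP eigenvalues : 0.790, 0.492, 0.488, 0.459, 0.195, 0.000
LSTM hidden units     : (100, 20)
LSTM learn rate / L2  : 0.01 / 0.0001  (defaults)
LSTM final train MSE  : 0.0025
training misclass.    : 0.0000

first trial: true='left' predicted='left' f_lda=+0.91 f_lstm=-0.91

Cross-validated performance
===========================
folds evaluated      : 20
positive class       : left
misclassification    : 0.0000 +/- 0.0000
sensitivity          : 1.0000 +/- 0.0000
specificity          : 1.0000 +/- 0.0000
kappa                : 1.0000 +/- 0.0000
```

The top CSP eigenvalue (0.79 ≫ 0.5) shows a strongly lateralized variance
contrast; the two fused features separate the classes with opposite
orientations (the LDA scalar is positive for *left*, the LSTM target
encoding makes *left* negative), and on these clearly separable synthetic
conditions the cross-validated error is zero. The 0.000 eigenvalue is the
common-mode direction removed by the average reference.

A CLI wraps the same operations:

```sh
opticalmi simulate --out data.npz --trials-per-class 60 --seed 7
opticalmi train    --data data.npz --out model.npz --seed 0
opticalmi predict  --model model.npz --data data.npz
opticalmi evaluate --data data.npz --folds 10 --reps 10 --out report.csv
opticalmi benchmark --data data.npz        # fused vs single-feature ablations
```

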