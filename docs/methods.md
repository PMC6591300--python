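# Methods

`opticalmi` implements a subject-dependent motor-imagery (MI) EEG decoder
that fuses two complementary descriptions of a trial — a stationary spatial
one and a temporal one — and classifies the pair with a kernel SVM. This
note records the model, the defaults and the numerical choices, and what the
synthetic benchmark does and does not establish.

## Signal model and preprocessing

A trial is a `channels x samples` epoch cut from a continuous recording a
fixed latency after the visual cue: by default the epoch spans 2 s starting
0.5 s post-cue, the interval in which sensorimotor desynchronization is
expressed. Each epoch is common-average referenced (CAR) and band-pass
filtered to 7–30 Hz, covering the mu and beta bands carrying the
class-discriminative power changes.

The band-pass is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`, even-reflection padding). Zero-phase filtering was chosen
because group delay on a 200-sample epoch would shift the class-relevant
power into neighbouring windows of the segmentation stage; the effective
magnitude response is the squared 4th-order response. Band edges are the
−3 dB points of the analog prototype. Epoch indices are 0-based and
half-open: a marker at sample `m` yields `[m + round(0.5 fs), m +
round(0.5 fs) + round(2 fs))`.

CAR removes the common-mode component, which makes every spatial covariance
rank-deficient by one; see *Numerical choices* for how the CSP eigenproblem
handles this.

## Common spatial patterns

For classes 1 and 2 with trace-normalized per-trial covariances
`C = E Eᵀ / tr(E Eᵀ)` and class means `C̄₁, C̄₂`, filters solve

    C̄₁ w = λ (C̄₁ + C̄₂) w .

Eigenvalues lie in (0, 1) and are complementary between the two class roles
(λ ↔ 1−λ). The bank keeps the `m` eigenvectors with the largest and the `m`
with the smallest eigenvalues; `2m = 6` filters throughout, a standard
choice for 2-class MI. Trace normalization makes the filters invariant to
global amplitude scaling. Features are `y = log(var(Wᵀ E))` with sample
variance (divisor `n−1`).

One-vs-rest banks (for the cascade) relabel the complement classes into a
single pooled class and reuse the same solver; the returned bank is
re-oriented so its eigenvalues always refer to the target class.

## The two features

**Spatial scalar.** The 6 whole-trial log-variances are reduced to one
scalar by the Fisher discriminant `w ∝ Sw⁻¹(μ₁−μ₂)` with pooled
within-class scatter, unit-norm `w`, and an offset centering the projection
between the class means, so a 0 threshold reproduces the equal-prior LDA
rule. The signed projection (not a posterior) is passed on.

**Temporal scalar.** Each trial is cut into `N` sliding windows of length
`l = 25%` and overlap `t = 5%` of the trial length (half-up rounding).
Window `j` starts at `j (l−t)`; if the last regular window stops short of
the trial end one extra window is re-anchored to end exactly at the last
sample. For a fixed step no integer `N` satisfies `(N−1)(l−t)+l = S` at,
e.g., `S=200, l=50, t=10`, so the end-aligned final window is what makes
"every sample used, no padding" achievable deterministically; the cost is
extra overlap between the last two windows. A second CSP bank is learned on
the pooled windows of the training trials (windows inherit their trial's
label), and each trial becomes an `N x 6` sequence of windowed log-variance
features.

The sequence feeds a two-layer LSTM (100 then 20 hidden units, standard
sigmoid-gate/tanh-cell recurrence, zero initial states) with a linear
read-out of the final hidden state. The network is trained as a *regressor*
against symmetric class targets −1/+1 by mini-batch SGD with momentum 0.9,
batch 16, 100 epochs, mean-squared-error loss, and L2 weight decay on the
weight matrices. Initialization is seeded: Glorot-uniform input maps,
orthogonal recurrent maps, zero biases except forget-gate bias 1. The
forward pass and full backpropagation through time are implemented in numpy
and validated against an independent scalar-loop evaluation of the gate
equations and against finite-difference gradients. Divergent training
(non-finite loss) raises immediately rather than clipping, since at this
network size divergence indicates a bad learn rate, not an exploding-tail
problem worth hiding.

Regression (rather than a softmax head) keeps the output a graded scalar:
its distance from ±1 carries confidence information that the downstream SVM
can exploit, which a hard label would discard.

## Hyper-parameter selection

The initial learn rate and L2 penalty are searched over `[1e-4, 1e-1]` and
`[1e-5, 1e-3]` in log10 coordinates (both spans are several decades). A
Gaussian-process surrogate (Matern 5/2, fitted noise) over the observed
objective drives expected-improvement acquisition on a 2048-point random
candidate set; 5 seeded uniform evaluations initialize the surrogate and
the default budget is 30 evaluations. The objective is the stratified
10-fold CV misclassification of the *deployed* pipeline on the training
split (a cheaper LSTM-only surrogate objective is available). The
unoptimized variant uses the defaults 1e-2 / 1e-4, the centres the search
boxes were placed around. Failed evaluations are recorded as NaN in the
trace and skipped by the surrogate; if every evaluation fails the optimizer
raises.

## Fusion and classification

The two scalars are z-scored with training statistics (their raw scales are
incommensurate) and fused by an RBF-kernel SVM with `C = 1` and
`γ = 1/(2 d · mean feature variance)` (`d = 2`), i.e. `γ = 0.25` on
standardized features — a conservative default appropriate for a
2-dimensional feature space. Exact ties at the decision boundary go to the
class with larger training prevalence, then lexicographic, for determinism.
Trained models serialize to a single `.npz` of named arrays plus a JSON
metadata block; prediction after reload is bit-identical because the
decision function is evaluated from the stored support vectors directly.

## Three-class cascade

For real-time-style operation with a non-task class (blinks, eye movement,
rest), two binary predictors are cascaded: stage 1 separates non-task from
pooled MI, stage 2 (trained on MI trials only, with its own spatial
filters) separates left from right; a trial labelled non-task by stage 1
never reaches stage 2. Before stage-1 training the non-task pool is
randomly subsampled to the total MI trial count, re-drawn per CV repetition
from the repetition's seed so no single lucky subsample is baked in. If
fewer non-task trials exist than MI trials, all are kept with a warning.

## Evaluation

Stratified k-fold cross-validation repeated `reps` times (default 10×10)
with independent seeded partitions; every trial is tested exactly once per
repetition and all fitting (both CSP banks, LDA, LSTM, hyper-parameters,
standardization, SVM) happens inside the training folds. Fold scores are
averaged — not count-pooled — into the aggregate, for misclassification,
sensitivity, specificity and Cohen's kappa alike; the positive class
defaults to the first class in sorted order and is configurable. Metrics
with an empty margin are reported as NaN rather than inventing a value.
Method comparisons use the classical paired t-test (two-sided p from the
t distribution with `n−1` degrees of freedom); all-zero differences raise
rather than returning `p = NaN` silently.

## Synthetic benchmark

The generator emulates the structure the decoder exploits, with known
ground truth:

* two narrow-band (8–12 Hz) amplitude-modulated sinusoidal sources with
  random per-trial frequency and phase, at two designated source channels;
  the class effect is a mirrored amplitude scaling giving a configurable
  between-class band-power ratio (default 4);
* a near-identity orthogonal full-rank mixing into all channels (QR of a
  perturbed identity, seeded), so the true unmixing directions are known;
* 1/f Gaussian background noise, independent per channel (`snr` = source
  amplitude / noise SD, default 3);
* non-task trials: no lateralized sources, sporadic Gaussian "blink" bumps
  (width ~0.1 s, frontal-dominant topography, peak 3.5× the strong source
  amplitude) on the same background;
* continuous records embed generated epochs behind cue markers exactly, so
  the epoching round trip is bit-exact.

Defaults are 8 channels, 100 Hz, 2 s trials. What this does **not** emulate:
volume-conducted realistic head geometry, non-stationary rhythms,
inter-subject variability, correlated noise, or real artifact morphology.
Passing the end-to-end bounds (≤10% CV misclassification two-class, ≤15%
three-class on these conditions) therefore demonstrates that the
implementation recovers known structure through the whole pipeline — not
that comparable rates will be obtained on real recordings, where
performance depends on subject and hardware.

## Numerical choices

* variance floor `1e-12` before any `log(var)` — degenerate (e.g.
  common-mode) filter outputs yield a finite constant feature and a warning
  instead of `-inf`;
* CAR rank deficiency: when the composite covariance's condition number
  exceeds 1e10 (the generalized eigensolver's singularity regime), its
  diagonal is loaded with `1e-9 · tr/channels` and a warning is emitted —
  a minimal perturbation; the whitening identity
  `W_fullᵀ(C̄₁+C̄₂)W_full = I` then holds to 1e-8 on full-rank data;
* eigenvalue ties broken by original index (stable sort); eigenvector signs
  fixed by making the largest-magnitude component positive;
* LDA scatter: shrunk 10% toward its diagonal when its condition number
  exceeds 1e8 (n ≈ 180, d = 6 can be marginal); identical class means raise
  a degenerate-separation error;
* every stochastic step (generation, initialization, shuffling, fold
  partitions, subsampling, acquisition) flows from explicit integer seeds;
  two runs with the same seeds are bit-identical, including serialized
  model files.

## Problem sizes

The test suite and the reproduction script run the synthetic study at
100 trials/class (two-class, 10×10-fold CV), 50 trials/class + 100 non-task
(cascade, 10-fold), 200 trials/class for spectral/oracle checks, and
budget-25 optimizer runs against a 25-draw random-search baseline over 10
seeds. These sizes give stable estimates on the separable conditions while
keeping a full run in the minutes range on one core.

## Known limitations

* The LSTM trains on CPU in numpy; it is sized for the 5-window × 6-feature
  sequences of this pipeline, not for long sequences or large batches.
* `N` (windows per trial) must be equal across trials of a dataset; trials
  of mixed length are not supported.
* The cascade reports 3-class misclassification only; per-class
  sensitivity/specificity are not defined for the pooled stage.
* EDF export writes plain EDF (16-bit, one-second records, integer sampling
  rates); EDF+ annotations are not written — markers travel separately.
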