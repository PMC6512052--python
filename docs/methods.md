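# Methods

## Segmentation model

A beat's analysis window is anchored on its annotated R-peak and bounded
by midpoints between neighbouring R-peak positions: with annotation
positions `pos[·]` (0-based samples, half-open ranges throughout),

    first = floor((pos[n-k+1] + pos[n-k+2]) / 2)
    end   = floor((pos[n+1]   + pos[n+2])   / 2)

for segment count `k` in [3, 7].  This covers ≈ `k` R–R intervals with the
reference beat near the centre, so the label (the reference beat's own
symbol) is attached to morphology *and* local rhythm context — the
shortened coupling interval of an APC or the compensatory pause after a
PVC is inside the window.  A reference beat needs annotated peaks at
relative positions `n−k+1`, `n−k+2`, `n+1`, `n+2`; otherwise it is
skipped, silently, since record edges always lose a few beats.  Context
peaks may be beats of any symbol (including excluded ones); only the
reference symbol must map to one of the five classes.  Midpoints round
down; the one-sample difference is immaterial after resampling.

## Normalization

Fixed network input requires fixed length: each window is resampled to
`(k−1) × samples_per_interval` samples (defaults: 100 per interval, hence
200–600).  The length is a pure function of the configuration, never of
heart rate or sampling rate.  Resampling is polyphase
(`scipy.signal.resample_poly`) with its FIR low-pass at the target
Nyquist, so decimation cannot alias R–R-scale content; a sine far below
the post-decimation Nyquist is reproduced to < 1e-2 away from the ~10
edge samples affected by filter transients.  Amplitude is z-scored per
window to remove inter-record gain and baseline differences; a window
with (near-)zero variance becomes all zeros instead of dividing by ~0.

## Network designs

All parameters live in a declarative `ModelSpec`.  An inception layer is
the naive form: parallel 1-D convolution branches (one per kernel size,
`filters_per_branch` each, ReLU) plus a stride-1 max-pool branch passing
its input channels through, concatenated along channels — no 1×1
reduction convolutions and no pool projection.  Branch outputs must share
the input's temporal length to concatenate, so branches use same-padding
(an even kernel pads the extra element on the right); the front
convolution stage of Design III is the only unpadded convolution
(15 filters, kernel 5, stride 1, then 2/2 max-pooling).  Expanded branch
kernels [10, 50, 100] reach across whole R–R intervals and are only
meaningful — and only permitted — in a layer computed directly on the ECG
input, where sample distance is still time; spec validation enforces
this (which also rules them out for Design III's inception layer).

Activations are ReLU after every convolution and hidden dense layer, with
a softmax output over the 5 classes; no dropout or batch normalization.
Initialization is Glorot-uniform from a single `default_rng(seed)` stream
consumed in construction order, so (spec, seed) → bit-identical
parameters.  The forward/backward passes are explicit numpy
(`sliding_window_view` + einsum); every layer's backward pass is verified
against central finite differences in the test suite.

## Training

Adam with lr 0.001, β₁ 0.9, β₂ 0.999, ε 1e-8 and bias correction —
"iteration 10" is read as 10 epochs over the training set, since 10
gradient steps could not traverse a 28k-beat training set even once.
Mini-batches of 100 with per-epoch seeded reshuffling; the final partial
batch is used.  Loss is categorical cross-entropy.  No early stopping,
schedules or augmentation.  The default split plan carries the study's
per-class train/test counts (NSR 10,000/5,000; LBBB 6,025/2,000; RBBB
5,728/1,400; APC 1,870/600; PVC 4,928/1,200), sampled without
replacement and disjoint at the beat level; when a class offers fewer
beats, both counts scale down proportionally with a warning.  Class
imbalance is left as sampled — the plan itself balances by construction.

## Evaluation conventions

Confusion matrices are truth-rows × prediction-columns in the fixed order
NSR, LBBB, RBBB, APC, PVC.  The per-predicted-class misclassification
error is **column-wise**, `100 × (column total − diagonal) / column
total` = `100 − PPV` of that predicted class; this is the definition that
reproduces every published error cell bundled in
`ecgbeats.published_matrices` (a row-wise reading does not).  Display
rounding is half-up to two decimals; internal values keep full precision;
a zero-denominator ratio is reported as not-applicable (`None`), never 0.
Binary normal/abnormal metrics collapse the matrix with "abnormal" as
positive: Acc=(TP+TN)/total, Se=TP/(TP+FN), Sp=TN/(TN+FP), Pp=TP/(TP+FP),
on the 0–100 scale.  The patient-specific relabel rule maps NSR→normal
always, APC/PVC→abnormal always, and LBBB/RBBB→normal exactly for the
seven MIT-BIH records whose baseline rhythm is bundle-branch block (109,
111, 118, 124, 207, 214, 232), configurable for other datasets.

## Synthetic data generator

Each beat is a sum of Gaussian P/Q/R/S/T waves with class-specific
centres, widths and amplitudes; classes differ the way their clinical
counterparts do structurally — LBBB/RBBB by widened/deformed QRS, APC by
an altered P wave plus a preceding R–R shortened by a prematurity
fraction (default 0.25), PVC by a wide bizarre QRS without P and a
following R–R lengthened by a compensatory factor (default 1.5).  R–R
intervals are `mean_rr` (default 0.8 s at 360 Hz) with Gaussian
jitter (CV default 0.05, clipped to [0.3, 2]×mean), and white
Gaussian amplitude noise (default 0.02 mV).  The default class mix
(0.351, 0.211, 0.201, 0.065, 0.172) mirrors the relative per-class
training counts of the split plan.  An APC drawn immediately after a PVC
is replaced by NSR: a single interval cannot be both a compensatory pause
and a premature coupling, and the replacement keeps both timing
signatures unconditionally testable.

What the generator does *not* emulate: baseline wander, electrode motion
artefacts, QT adaptation to rate, beat-to-beat morphology variability
within a class, inter-patient variation, or multi-lead projection.  Its
classes are far better separated than real MIT-BIH beats, so the
end-to-end pipeline test (≥ 90% held-out accuracy, in practice 98–99.5%)
validates the plumbing — segmentation, resampling, learning dynamics,
metric arithmetic — and says nothing about accuracy on real recordings.

## Problem sizes and numerical choices

The end-to-end run in the tests and the acceptance script uses 8 records
× 400 beats (≈ 3,200 windows at k=3, ≈ 2,340 of them training) and
Design I with 15 filters per branch (≈ 0.9 M parameters), chosen as the
smallest configuration that exercises every stage at the study's
hyperparameters (batch 100, 10 epochs).  The split plan is the study
plan; the per-class proportional fallback adapts it to the synthetic
pool.  Tolerances: probability rows sum to 1 within 1e-6; z-scored
windows have |mean| < 1e-6 and |sd − 1| < 1e-6; the variance guard is
1e-12; backprop matches finite differences within 1e-5.

## Known limitations

* WFDB support is read-only and covers formats 212 and 16, one channel at
  a time; enough for MIT-BIH-style records, not a general WFDB library.
* No QRS detection: unannotated signals cannot be segmented.
* The numpy networks are single-threaded-friendly and small; they are not
  a platform for large-scale training.
* Published three-class comparison matrices are consumed as printed
  counts; the competitor classifiers themselves are not reimplemented.
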