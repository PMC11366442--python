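# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind the package, in the order data flows through it.

## Problem setting

A beat classifier sees a fixed-length amplitude window centered on an
annotated R-peak and outputs a rhythm class.  Two regimes are supported:
five-class (N, L, R, A, V) on 360-sample windows cut from annotated 360 Hz
records, and binary (Normal/Abnormal) on 187-sample pre-segmented rows.
R-peak positions always come from annotation files; QRS detection is out of
scope.

## Synthetic generator

`ldcnn.synthetic` emulates the *statistics* of the benchmark inputs, not
cardiac electrophysiology.  Each class is a fixed template of Gaussian
bumps (P wave, Q dip, R spike, S dip, T wave) with class-specific QRS
width/amplitude, P-wave prominence and T-wave polarity; templates are
pairwise distinguishable (normalized zero-lag cross-correlation < 0.99,
enforced by test).  Records place beats at jittered regular intervals
(mean RR 0.83 s ≈ 72 bpm, jitter ≤ 10%, default class mix
N 75% / L 8% / R 7% / A 7% / V 3% matching the real archive's skew) and add
the three classic interference sources: baseline wander (0.3 Hz sinusoid,
0.1 mV), powerline hum (60 Hz, 0.02 mV) and white noise (σ = 0.03 mV).
Class counts use deterministic largest-remainder allocation so tests can
assert them exactly; all randomness flows from one integer seed and output
is bit-reproducible.

What this does *not* emulate — heart-rate variability, rhythm-level
(inter-beat) arrhythmia context, electrode artefacts, inter-patient
morphology variation, class overlap.  Passing learning tests therefore
demonstrate that the pipeline and optimizer are correct, not that real-data
accuracies transfer; the synthetic classes are separable by construction.

## I/O

A minimal WFDB codec (`ldcnn.wfdbio`) reads headers, signal formats 212
(the 12-bit packing of the 360 Hz archive), 16 and 32, and MIT-format
annotation files; beats are separated from non-beat markers (rhythm
changes, quality flags, waveform boundaries) by the standard code table.
The writer emits format 32 at 1e6 ADU/mV, bounding round-trip quantization
error at 0.5e-6 mV.  Segmented mode reads/writes headerless CSV rows of
``window_length`` samples plus one integer label, rejecting ragged or
non-numeric rows with the row number.

Vocabularies: `mitbih5` keeps exactly the five used beat codes and excludes
every other symbol (rather than pooling them into a sixth class);
`ptb2` maps the normal code to Normal and every other *beat* code to
Abnormal.  Exclusion is total and audited: assigned + excluded = all
annotations.

## Conditioning

* **Denoising** — 4-level discrete wavelet decomposition, db4, periodized
  (so the transform is orthonormal and energy cannot grow under
  coefficient shrinkage), soft universal threshold
  σ√(2 ln N) with σ = median(|d₁|)/0.6745 from the finest detail level.
  The method is named by the protocol but none of its parameters is, so
  wavelet, level and rule are configuration with these defaults; denoising
  defaults to on for raw records and is skipped for pre-segmented tables
  (already conditioned upstream).  `threshold_rule="none"` gives the pure
  round trip (used for idempotence tests).
* **Normalization** — z-score with population σ, per record before
  segmentation (segmented tables arrive without record context and are
  normalized upstream).  Constant signals are a hard error, not NaN.
* **Segmentation** — window [r − pre, r + post) per annotation;
  pre = post = window/2 by default since the protocol never states the
  split and a symmetric window covers the full PQRST neighborhood.
  Boundary-violating and excluded beats are dropped and counted in the
  dataset's `meta`; windows are verbatim slices of the conditioned signal.

## Dataset operations

Balancing resamples every class to one target (5,000 in the published
protocol): minorities up with replacement, majorities down without, seeded.
The published stage order balances **before** the 80/20 split, which lets
duplicates of one source beat reach both sides; the pipeline follows that
order by default, *measures* it (`duplicate_provenance_in_test` in the
manifest), and offers `split_before_balance=True` for leakage-free
evaluation.  Splitting uses stratified sampling with
|test| = ⌈f·n⌉ — the rounding that maps 14,552 → 11,641/2,911 at f = 0.2.
One-hot encoding is parametric in class order; the binary head uses a
single 0/1 column (sigmoid output) rather than two-column one-hot.

## Networks

Architectures are data (`ArchitectureSpec`), with symbolic shape
propagation as the single source of geometric truth: same-padded conv
preserves length, valid conv gives L − k + 1, pooling gives
⌊(L − p)/s⌋ + 1, flatten gives L·C.  The binary architecture's published
table prints pooling stride 1, but its own output-shape column
(179→89, 85→42, 38→19) is only consistent with stride = pool = 2; the
shapes win.  The five-class dense-35 layer lists no activation; ReLU is
used, matching the rest of the stack.

The engine is NumPy: conv forward/backward as a kernel-position loop of
GEMMs, float32 throughout, Glorot-uniform init from an explicit seed,
Adam (β₁ 0.9, β₂ 0.999, ε 1e-7).  Softmax/sigmoid are fused into the loss
on logits for stability and applied only at prediction; dropout uses
inverted scaling and is inert at inference.  Optimizer, learning rate,
batch size and loss are not stated in the published protocol; the declared
defaults are Adam 1e-3, batch 32, categorical/binary cross-entropy, all
configurable.  Determinism: same seeds ⇒ identical parameters, loss
curves and predictions (single-threaded CPU arithmetic).

Training monitors the test set per epoch by default (mirroring the
published accuracy/loss curves); `stop_at_accuracy` implements an ordinary
convergence stop on the monitor metric.

## Metrics

Per-class metrics one-vs-rest from the multi-class confusion matrix —
the only reading under which a per-class *accuracy* (TP+TN over total) is
distinct from recall, as in the published per-class tables.  Aggregate
accuracy is the overall correct fraction; other aggregates are macro means
by default (micro available).  The published aggregate row for the
five-class run (precision 99.60, recall 99.40, F1 99.60) is internally
inconsistent with F1 = 2PR/(P+R) ≈ 99.50, so no specific averaging scheme
can reproduce it; this package keeps its own averages self-consistent.
Zero-denominator cells report 0 with a flag, never NaN.  All metric
formulas are cross-checked in tests against a brute-force recount from raw
label pairs.

## Problem sizes and budgets

The learning-sanity checks train on 5,000 beats per class (25,000 windows
five-class, 10,000 binary) at noise σ 0.05 mV, batch 128, at most five
epochs with the 0.995 convergence stop — about a minute of single-core
compute for the pair; the smaller unit tests use hundreds of beats.  The
full-data reproduction (80/30 epochs on the real archives) is provided as
`examples/reproduce_physionet.py` and is expected to land within about a
percentage point of the published headline accuracies given the unstated
optimizer settings.

## Known limitations

* No QRS detection, multi-lead fusion, or rhythm-level context.
* The synthetic generator's separability makes near-perfect scores easy;
  it cannot expose inter-class confusion behavior.
* The NumPy engine targets these two architectures' layer set; it is not a
  general autodiff framework (no residual connections, no batch norm).
* WFDB support covers the subset the pipeline needs (single .dat per
  record, formats 212/16/32, MIT annotations).
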