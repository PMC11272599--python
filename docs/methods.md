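# Methods

## The classification problem

Shockable ventricular arrhythmias — ventricular flutter (VFL), ventricular
fibrillation (VF), torsade de pointes (VTTdP) and high-rate monomorphic
ventricular tachycardia (VTHR) — must be recognised within seconds, e.g. by an
implanted cardioverter-defibrillator.  The package classifies 2-s single-lead
ECG fragments into these four classes by converting each fragment into a
time–frequency image and applying a small hybrid convolutional/recurrent
network.

## Continuous wavelet transform

The transform is `C(a,b) = a^{-1/2} ∫ f(t) ψ*((t−b)/a) dt` with the Morlet
mother wavelet `ψ(t) = e^{2πit} e^{−t²/(2σ²)}`.  Notes on conventions:

- The **complex conjugate** of ψ is taken inside the integral (the standard
  CWT definition).  Because the carrier has unit modulus this does not change
  coefficient magnitudes, which are all that the scalogram uses.
- **σ = 1** by default; the `e^{2πit}` carrier fixes the wavelet's center
  frequency at 1 cycle per unit wavelet time, so the pseudo-frequency probed
  at scale `a` seconds is `1/a` Hz.
- The discretised integral sums over sample times with Δt = 1/fs and
  truncates the wavelet where its Gaussian envelope falls below 1e-8 of the
  peak.  Three implementations exist and are held equal by tests: the literal
  double-loop summation (`cwt_direct`, the reference), a per-scale FFT
  convolution (`cwt`), and a batch transformer caching kernel FFTs
  (`CWTTransformer`, used when converting thousands of fragments).  Agreement
  is verified to 1e-8 relative Frobenius error; an independent cross-check
  against PyWavelets' `cmor` wavelet confirms the field shape up to that
  library's amplitude convention.
- **Scale grid**: 64 log-spaced scales spanning pseudo-frequencies 1–50 Hz.
  This brackets every rhythm fundamental the generator produces (2.5–8 Hz)
  and the dominant energy of wide QRS complexes.
- **Rendering**: magnitudes (not power; `--log` switches to log-magnitude)
  are min–max normalised **per image**, mapped through matplotlib's `jet`
  (the MATLAB-style rainbow used for scalograms throughout this literature),
  oriented with high frequencies at the top, resized bilinearly to 227×227
  and quantised to 8-bit RGB.  Per-image normalisation makes the image
  invariant to overall signal amplitude; a constant coefficient field maps
  to the colormap's value at 0.

## Synthetic fragment generator

The generator emulates the **morphological contrasts** that define the four
classes, not cardiac electrophysiology.  Defaults: fs = 250 Hz (the sampling
rate of the Holter recordings behind the public high-risk fragment
database; configurable), duration 2 s, amplitude 1 mV, additive white
Gaussian noise with sd 0.05 mV — a realistic noise floor for Holter-quality
recordings.

- **C1 (VFL)**: fundamental drawn in 4–6 Hz, 90% fundamental + 10% second
  harmonic — a near-sinusoid.
- **C2 (VF)**: six sinusoids with frequencies drawn in 3–8 Hz, random phases
  and independent slow (0.4 Hz) amplitude drifts; amplitudes normalised so
  the worst-case sum is 1.  No stable period exists by construction.
- **C3 (VTTdP)**: a wide-pulse train at 3–5 Hz whose amplitude envelope
  `1 − (depth/2)(1 − cos 2π f_mod t)` swings between (1−depth) and 1 at
  f_mod ∈ 0.2–0.5 Hz with depth 0.8, and whose polarity flips at the envelope
  minima — the characteristic twisting about the isoelectric line.
- **C4 (VTHR)**: a strictly periodic wide-pulse train at 2.5–4 Hz with
  constant amplitude and ≤1% timing jitter (encoding the regular-vs-chaotic
  contrast with C2).

The "QRS" lobe is a Gaussian first derivative with 40 ms width: visually and
spectrally similar to a ventricular complex, with no P/T waves (absent in
these rhythms anyway).  Every fragment draws from an RNG stream keyed by
`(seed, class, index)`, so datasets are reproducible and extending a class
never changes existing fragments.

What the generator does **not** model: baseline wander, electrode artefacts,
mains interference, heart-rate variability within a fragment, amplitude
differences between leads, or transitions between rhythms.  Tests passing on
this data demonstrate that the pipeline's machinery is correct and that the
model can learn genuinely different time–frequency morphologies; they do not
certify clinical performance, which requires the real fragment databases.

A guard test verifies the fixtures are not degenerate: a three-threshold rule
classifier (envelope coefficient of variation → C3; weak autocorrelation
periodicity → C2; low crest factor → C1; otherwise C4) must reach ≥80%
accuracy on 400 noisy fragments — it reaches ~90%.

## SMOTE

Oversampling operates on the **raw 1-D signals before** the wavelet
transform: interpolating two signals and then transforming always yields a
valid scalogram, whereas interpolating rendered images can produce pixel
fields no signal generates.  (`smote_vectors` accepts arbitrary vectors, so
image-domain interpolation is available for comparison.)  k = 5 neighbours
(the canonical setting), Euclidean distance on the raw sample vectors,
brute-force exact k-NN (class sizes are hundreds at most), base fragments
visited round-robin, neighbour index and interpolation factor u ~ U[0,1]
from a stream keyed by `(seed, class)`.  When a class has n ≤ k members, k is
clipped to n−1 and logged; n < 2 is an error.

Two balancing policies exist because the ordering of oversampling and
splitting materially changes what the test set measures:

- `paper` (default): oversample the whole dataset to the per-class target,
  then split 80/10/10.  This reproduces the published bookkeeping
  (578 real → 4,000 total → 3,200/400/400) but lets synthetic points whose
  parents span the split boundary leak information into the test set.
- `safe`: split first, oversample the training partition only.  Honest test
  metrics, different totals.
- `off`: keep the raw imbalanced distribution (the imbalanced-baseline
  experiment).

## Network

Input H×H×3 (227 default; any size ≥ 32 that survives five halvings).  Five
conv blocks (3×3, same padding, ReLU, 2×2 max-pool) with 16/32/64/64/128
filters; dropout 0.25/0.25/0.5 after pools 3–5; global average pooling;
reshape of the 128-vector to a 128-step sequence of scalar features; a
128-unit GRU read out at its final state; a 128-unit ReLU dense layer; a
4-way softmax.  The published architecture fixes the layer inventory and
order and an overall budget of "208 thousand" parameters but not the
per-layer widths; the defaults above satisfy every structural constraint at
201,316 trainable parameters (closed form and weight tally agree exactly).
Ablation variants: `cnn_only` (GAP feeds the dense head directly) and
`gru_only` (raw image rows as a height-step sequence of width×3 features).

The reshape semantics deserve a note: global average pooling leaves a single
feature vector, and the only reshape that gives the GRU a non-trivial
sequence is length-128-by-1 — the GRU then integrates an ordered scan over
feature channels.

**Bias conventions.**  The gate equations are bias-free; the reference
`gru_step` follows them literally and is the oracle for gate arithmetic.
The trainable GRU layer carries one bias per gate (the usual framework
default); zeroing those biases makes one layer step equal the reference to
float32 precision, and `count_parameters(cfg, include_biases=False)` reports
the bias-free convention.

**The engine.**  No deep-learning framework is used: `_layers` implements
forward and backward passes in NumPy (float32).  Convolutions are expressed
as nine shifted-slice matrix products per pass, so all heavy arithmetic is
BLAS; max-pool routes gradients to the first maximal element of each window
(argmax order); the GRU backpropagates through time with the final-state
gradient only.  Layer gradients are verified against finite differences
(in the affine regime for kinked layers, exactly for pooling) and the conv
forward pass against `scipy.signal.correlate`.

**Optimiser.**  Adam with the legacy per-update decay
`lr_t = lr0 / (1 + decay·t)` — the meaning `decay=1e-6` had in the framework
generation the published training setup names.  (Decoupled weight decay is a
different operation and is deliberately not what this knob does.)  Defaults:
lr 0.001, decay 1e-6, batch 16, categorical cross-entropy, 400 epochs at
full scale.  Checkpoint selection defaults to best validation accuracy
(earliest epoch on ties); `last` is available and is used inside
cross-validation, which has no validation split.

## Evaluation protocol

Split sizes are `round(N·ratio)` per stratum for validation and test with the
remainder to train — on the balanced 4,000 this gives 3,200/400/400 with
800/100/100 per class; on the raw 578 it gives 462/58/58.  Metrics are
one-vs-rest per class: precision, recall (sensitivity), specificity
TN/(TN+FP), F1; macro averages are unweighted class means (the convention
consistent with a balanced test set); empty denominators report 0.  ROC
curves and trapezoidal AUC come from scikit-learn on the softmax scores
(equal scores collapse into a single threshold step).  Cross-validation is
stratified k-fold (k = 5): every sample is tested exactly once; the report
lists per-fold accuracy/loss and their means.  The sweep trains one seeded
model per {learning rate, decay, batch size} cell and sorts by validation
accuracy, ties broken toward smaller batches.

## Explanation

LIME-style surrogates with a regular-grid superpixel partition (block 32 →
8×8 = 64 superpixels at 227×227).  Scalograms are smooth, so a content-aware
segmenter (SLIC etc.) adds a dependency without changing the story; the
`SuperpixelMap` interface accepts any partition.  Defaults: n = 1000
perturbations, each superpixel kept with probability 1/2, masked regions
filled with the whole-image mean colour (the common default; black or blur
would also be defensible), kernel width 0.25 on cosine distance to the
unperturbed mask, ridge penalty 1.0.  A planted-superpixel oracle (a
"model" that responds only to one region) is recovered 20/20 seeds in tests.

## Problem sizes in tests and the acceptance script

The published experiments train 400 epochs on 4,000 227×227 scalograms.  The
package's own verification budget is desk-scale by design: the end-to-end
check uses 1,000 fragments (250 per class), 64×64 scalograms, 30 epochs and
the default architecture, reporting the median test accuracy over three
training seeds (threshold 0.90); transform equivalence uses 64-sample
fragments where the literal double-loop reference is cheap.  These sizes are
the package's standing definition of the scaled-down benchmark so results
are comparable across runs.

## Known limitations

- The synthetic benchmark is easier than real ECG: clean class-specific
  spectra, no artefacts, no inter-patient variation.  Published-scale
  accuracy on the real databases is out of scope here.
- The WFDB reader supports signal formats 16 and 212 and MIT beat
  annotations — enough for the public databases this pipeline targets — not
  the full format zoo.
- `paper`-mode balancing leaks synthetic-neighbour information across the
  split; it exists to reproduce the published bookkeeping and is documented
  as such.  Use `safe` for honest estimates.
- Training is single-threaded NumPy: fine at desk scale, not meant for
  227×227 × 400-epoch runs.
- Figure-generation (confusion-matrix and ROC plots) is intentionally left
  to the caller; reports serialise to JSON/CSV.
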