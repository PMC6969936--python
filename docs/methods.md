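# Methods

This note documents the models, defaults and numerical conventions behind
`eegdecode`, and what the synthetic-data demonstrations do and do not show
about real recordings.

## Experimental design model

The package models a retro-cue imagery experiment with four target images
(2 categories × 2 exemplars). An imagery trial is: 1000 ms fixation, four
1500 ms stimulus presentations, 1000 ms fixation, a numerical retro-cue
(1–4), a self-paced mouse click that starts a 3000 ms imagery period, and
an 8-alternative response screen (the four targets and their horizontal
mirror images). Each block holds all 24 orderings of the four targets and
is preceded by rapid serial streams of 56 images at 200 ms SOA.

Target counterbalancing is implemented as a Latin square: each ordering
receives a random cyclic position schedule over blocks. This guarantees
exactly — not just in expectation — that (a) within a block every ordering
appears once, (b) a given ordering's target differs in every block, and
(c) every (stimulus, serial position) pair is targeted equally often
(6 times in the 4-block design). The protocol description underdetermines
how "randomised" allocation interacts with the different-target-per-
sequence constraint; the Latin square is one consistent reading, chosen
because it enforces the stated marginal balance for every seed.
Orderings are canonicalized lexicographically before allocation so a seed
fully reproduces a design. The mirrored-distractor screen layout is
modelled only as response identities (mirror/original); on-screen position
is never used by any computation.

Behavioural summaries report fraction correct, the share of errors that
chose the mirrored target, the mirrored-target share of all responses, and
reaction-time mean/SD with a 0.5 s right-open histogram.

## Synthetic cohorts

The generator produces continuous multichannel recordings with the same
event timeline the design prescribes, so the preprocessing and epoching
code paths are exercised exactly as they would be on real data.

- **Class structure.** Each exemplar has a unit-norm spatial pattern
  `normalize(0.5 · c_cat + 0.5 · e)` mixing a category-level and an
  exemplar-level random direction, so category and exemplar contrasts are
  simultaneously decodable; stream filler images use the category mean
  pattern. The evoked response is the pattern times a half-cosine bump
  (default onset 100 ms, duration 300 ms after each stimulus onset),
  scaled by `evoked_snr` relative to the broadband noise RMS. The bump is
  smooth with compact support, so onset-recovery tests are not confounded
  by filter ringing.
- **Imagery signal.** Added at the mouse click with per-trial Gaussian
  latency jitter (default SD 200 ms), reflecting that image generation is
  not tightly time-locked. Its default amplitude is **zero**: the default
  cohort is a true imagery null, which is the regime the inference
  machinery must not convert into false positives.
- **Noise.** 1/f pink noise (exponent 1, RMS 1 µV), white sensor noise
  (0.5 µV), and a 50 Hz mains sinusoid (0.5 µV, random phase per channel).
- **Behaviour.** Response accuracy 0.92; errors split 1/3 mirrored target,
  2/3 other originals. Cue-to-click RTs are log-normal with median 2 s
  (shape 0.75). Questionnaire ratings are drawn around a subject-level
  vividness trait uniform on [2.0, 4.6], so cohort totals span enough of
  [32, 160] to exercise the median split.
- **Calibration.** `evoked_snr = 1.0` was chosen once so that peak vision
  decoding on default cohorts falls in the 0.6–0.9 band typical of strong
  visual category effects; no printed empirical accuracy is targeted.

Determinism: a cohort is a pure function of its config; per-subject
generators are spawned from `numpy.random.SeedSequence(seed)`.

What the generator does **not** emulate: volume conduction (no leadfield
or dipole geometry — patterns are arbitrary directions in channel space),
eye-blink/muscle artifacts, inter-subject latency differences, amplitude
non-stationarity across a session, and any realistic relationship between
reported vividness and signal strength (the two are independent unless
configured otherwise). Passing tests therefore demonstrate that the
*analysis chain* is correct and calibrated — unbiased under nulls, able to
recover injected effects at the right latency — not that real imagery
EEG would behave this way.

A fast epoch-level generator (`simulate_labelled_epochs`) produces the
same injection model directly on an epoch grid, skipping the continuous
timeline; it exists for statistical calibration studies that need hundreds
of replicate cohorts.

## Preprocessing

Order: downsample 1000 → 250 Hz (polyphase FIR anti-alias; event onsets
floored), 0.1–100 Hz zero-phase Hamming FIR band-pass (transition widths
0.1 Hz and 10 Hz — the narrow high-pass edge needs a ~33 s kernel, which
is why filtering is applied to continuous data only), then 50 Hz line
removal, then epoching. No baseline correction, re-referencing or
artifact rejection.

Line removal defaults to sliding-window sinusoid regression: a sine/cosine
pair at 50 Hz is fit by least squares in 8 s windows (50 % overlap, Hann
cross-fade) and subtracted, adapting to slow amplitude drift while leaving
neighbouring frequencies untouched. The 8 s window keeps the fit's own
sampling noise below 2 % RMS on line-free data (a 4 s window removes
~2.2 % from pure noise, which is why the longer default was adopted). A
conventional zero-phase IIR notch is available via
`PreprocessConfig(line_method="notch")`. Note the regression is
time-varying, so it does not commute exactly with the band-pass; the
notch does (up to edge effects).

Epochs are half-open windows `[−300, +1500)` ms around the alignment
event — stimulus onset for pattern/vision epochs, cue onset and mouse
click for the two imagery epoch types — giving exactly 450 samples at
250 Hz. Pattern-estimator epochs intentionally overlap the following
seven 200 ms presentations, as in any rapid-stream design. Epochs
extending past the recording are dropped and counted in the log. When the
cue-to-click RT is short, cue-locked and response-locked epochs share raw
samples; this mirrors the task and is asserted in tests.

## Decoding

The classifier is a binary shrinkage-regularized linear discriminant:
pooled within-class covariance `S` (denominator n − 2), shrunk as
`S_λ = (1 − λ)S + λ(tr S / p) I` with λ = 0.01 by default (the standard
regularized-LDA default in MVPA toolboxes; exposed in
`ClassifierSpec`), weights `w = S_λ⁻¹(μ₁ − μ₀)`, threshold midway between
the projected class means. Points exactly on the boundary go to class 0,
deterministically. The implementation fits all time points of a fold in
one batched pass (einsum covariance + batched solve).

Features at time *t* are the 3 samples centred on *t* across all
channels. A 3-sample window at 250 Hz is labelled **12 ms** (3 × 4 ms
sampling interval) following the field's counting convention, although
first-to-last span is 8 ms. Time points whose window would leave the
epoch are omitted, not padded.

Schemes:

- `leave_one_chunk_out` — hold out one chunk (one imagery sequence for
  vision epochs, one stream for pattern epochs). Vision decoding pools all
  four serial positions.
- `leave_two_exemplar_out` — for imagery epochs: hold out all epochs of
  one exemplar per category (2 × 2 = 4 folds), training on the
  complementary exemplars. All epochs of the held-out exemplars are
  tested (the alternative single-epoch reading would discard test data);
  stream filler images, which have no exemplar identity, always stay in
  training.
- Exemplar-within-category contrasts require a single-category epoch set
  and use chunk-wise CV (leave-two-out is undefined within a category).
- `split_half_cross` / `leave_one_out_cross` — train on one condition,
  test on another; the leave-one-out variant excludes, per tested imagery
  chunk, all training epochs from the same experimental trial, avoiding
  autocorrelated train/test pairs.
- Temporal generalization trains at each time point and tests at all
  others; its diagonal equals split-half cross-decoding at matched times
  to machine precision because both share the fitting path.

Folds with an empty training class are skipped with a logged warning;
accuracy is the unweighted mean over usable folds.

## Inference

**Group level.** One-sample sign-flip Monte-Carlo test on subject
(accuracy − 0.5) curves. Per time point the across-subject t statistic is
enhanced with TFCE over the 1-D time axis (E = 0.5, H = 2, dh = 0.1); the
null distribution of the maximum enhanced score comes from 10,000 random
sign flips of whole subject curves. Corrected p-values use the smoothed
estimator (1 + b)/(1 + n), so no p is ever zero; an exact mode enumerates
all 2ⁿ flips for small groups. Testing is one-tailed (above chance). A
cluster-mass statistic with forming threshold t = 1.645 is available
behind `StatsConfig(cluster_stat="mass")`; TFCE is the default because it
needs no forming threshold. t values are clipped at ±20 before
enhancement: with few subjects a near-zero sample variance produces
astronomically large t, and the clip — a fixed monotone transform applied
identically to observed and null curves — keeps the threshold integration
bounded without affecting validity. Zero-variance time points score 0
with a warning. Note the sign-flip minimum attainable p is 2⁻ⁿ⁺¹-ish:
groups of 4 can never reach p < 0.05, by construction rather than by bug.

**Single subjects.** The decoding procedure is re-run under 1000 label
permutations (labels shuffled freely across epochs; the chunk structure
is kept for fold construction only). p(t) is the smoothed rank of the
observed accuracy; Benjamini–Hochberg FDR (q = 0.05) is applied across
time points. If fewer distinct label arrangements exist than requested
permutations, sampling is with replacement and logged.

**Vividness split.** Subjects are grouped by the median of their
eyes-open vividness subscore; subjects exactly at the median are
excluded, and both groups must retain ≥ 2 members. The high-minus-low
difference is tested with a pooled-variance two-sample t, TFCE-enhanced,
against 10,000 random group relabelings, one-tailed (difference > 0).

Cluster inference is over time only; channels are already collapsed by
the classifier.

## Problem sizes used in tests and the acceptance script

Simulations are scaled for a single CPU as the package's own test-design
choice: reduced channel counts (6–16), one experimental block, and the
epoch-level generator for replicate-heavy calibrations. Specifically: the
family-wise error calibration uses 200 replicate null cohorts of 8
subjects (32 epochs each, 1000 Monte-Carlo flips); effect-latency
recovery uses 16 subjects with a strong (SNR 3) pattern injected at
100–400 ms, requiring the group onset within ±24 ms (6 samples); null
cohorts of 96 trials × 8 subjects must keep the across-subject mean
within 3 binomial standard errors of 0.5 at every time point. The
acceptance script simulates an 8-subject, 16-channel, one-block cohort
through the full continuous pipeline with the full 10,000/1000 iteration
counts. Timing parameters, counterbalancing, filter settings and all
statistical settings are never reduced.

One calibration fact worth knowing: cross-validated accuracy on chunked,
temporally correlated (1/f) data has per-time-point dispersion slightly
above the naive binomial standard error (about 1.3× at these sizes),
because fold predictions share training data and slow noise components
span the epoch. Aggregate checks in the tests are sized accordingly.

## Known limitations

- EDF files are read (through MNE, events from a sidecar TSV when the
  file carries no annotations) but not written; the native container is
  HDF5.
- Binary contrasts only — the design's four stimuli are always analysed
  as 2-class problems (category, or exemplar within category), as in the
  modelled protocol; no multiclass decoding.
- No searchlight or channel-subset analyses, no nonlinear classifiers,
  no spatiotemporal (channel × time) clustering.
- The regression line-noise cleaner assumes a stable line *frequency*;
  only amplitude/phase may drift.
- `allocate_targets` requires the block count to be a multiple (or
  divisor) of the sequence length; unbalanced designs are rejected rather
  than approximated.
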