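# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, and what the synthetic data can and cannot
establish.

## Problem setting

During intermittent photic stimulation, photosensitive patients produce
photoparoxysmal responses (PPRs): epileptiform discharges of very variable
duration (a tenth of a second to several seconds) within otherwise ordinary
EEG.  Framing detection as classification of 1-second sliding windows (90%
overlap, 500 Hz → 500-sample windows, 50-sample step) yields a minority-class
share of only a few percent.  The package's purpose is the machinery that
makes learning under that imbalance workable: minority-class augmentation by
segment recombination, majority-class undersampling inside a repeated
cross-validation scheme, and a dual test-set design that measures what the
augmentation changes.

## Synthetic EEG generator

The generator emulates the statistical structure of photic-stimulation
recordings, not their physiology.

**Background.** Each channel is independent 1/f ("pink") noise — power
spectrum ∝ 1/f^α with α = 1 by default — scaled to 10 µV standard deviation,
plus an alpha-band sinusoid (10 Hz, 5 µV peak) with a random per-channel
phase.  Units are nominal microvolts; absolute calibration is irrelevant
because every downstream feature is scaled per training fold.

**Discharges.** Each recording receives `ppr_event_rate` (default 3)
spike-and-wave events at uniformly random, non-overlapping positions (≥ 1 s
apart), with durations uniform in 0.1–5 s.  The waveform is a 3 Hz cycle of a
slow sinusoidal half-wave plus a sharp Gaussian spike (σ = 15 ms), tapered
over 50 ms at the edges.  Events are synchronous across channels — cut-point
coherence across channels is an assumption the augmentation operator relies
on — but their per-channel amplitudes vary (uniform 0.3–1.7× around the event
amplitude).  The spread matters: a spatially *uniform* discharge would cancel
exactly under the average montage, which no real generalized discharge does.
Event amplitude is `ppr_amplitude_gain` (default 3) × the 10 µV noise scale,
with a ±25% per-event jitter standing in for morphological variability.

**Sparsity.** With 3–5-minute recordings and 3 events each, windowing yields
a PPR share of roughly 4–5%, matching the imbalance regime the pipeline is
designed for (the worked example in the README measures 4.65% on 10
recordings).

What the generator does **not** model: flash-frequency dependence, PPR
type morphologies (occipital spikes vs. generalized poly-spike-wave),
inter-patient heterogeneity, artifacts (blinks, muscle), or volume-conduction
channel correlations.  Consequences for interpretation: a detector's absolute
performance here says little about clinical performance; the pipeline-level
comparisons (augmented vs. not, Test 1 vs. Test 2, configuration grids) are
the meaningful outputs, because both arms face identical data.

## Windowing and the case taxonomy

Coordinates are 0-based and half-open everywhere.  A window is PPR iff it
shares ≥ 1 sample with an annotated interval.  The positional case of a PPR
window relative to its discharge ([s, e) vs. window [w, w+L)): *whole* if
s ≥ w and e ≤ w+L; *onset* if only the start is inside; *offset* if only the
end is inside; *middle* if the discharge spans the window.  A window meeting
two discharges takes the case of the larger overlap (ties to the earlier
one) — a situation the 1-second-spacing constraint makes rare in synthetic
data but that closely spaced real events could produce.  Trailing samples
that do not fill a window are discarded.

## Recombination augmentation

Parents must share a positional case; mixing cases would splice, say, a
discharge end into a window whose other half contains a discharge start,
producing physiologically meaningless hybrids.  With n = 3 cut-points on
500-sample windows (the only geometry used in practice; the operator checks
divisibility for other n), segments alternate A, B, A, B and each cut-point
is smoothed with the fixed convex 5-sample ramp (¾/¼, ½/½, ¼/¾).  The outer
two rows of the ramp restate what alternation already guarantees and are
implemented as written.  Consequences, all property-tested: recombining a
window with itself is the identity; every child sample lies between the
parents' values; outside the ±2-sample neighbourhoods the child equals its
designated parent exactly; the parent-of-origin pattern is identical across
channels.

Smoothing is applied at all cut-points unconditionally, and parent pairs are
drawn uniformly without replacement within a pair (pairs may recur across
children).  Parents may come from different recordings.  Balancing assigns
`total/4` children per case, remainder to the first cases in the fixed order
onset, offset, middle, whole.

`spectral_similarity` reports band-wise (1 Hz bands, 1–50 Hz) child power
against the parent mean as a diagnostic; it is deliberately not a filter —
the operator's output is used as-is.

## Feature stage

The montage subtracts the instantaneous cross-channel mean (output columns
sum to zero).  Analysis uses channel Fz only — the frontal midline site most
informative for generalized discharges when a single channel must be chosen.
Filtering is a 2nd-order IIR notch at 50 Hz (Q = 30) and a 4th-order
Butterworth band-pass 1–50 Hz, both applied forward–backward for zero phase;
orders and the zero-phase choice are this package's decisions.  On 1-second
windows the notch's steady-state null is partly masked by edge transients;
the contract tested is < 10% residual RMS at 50 Hz and ≤ 20% deviation at
10 Hz.

The 32 features (7 statistical, 8 temporal, 17 spectral) follow common
time-series-feature-library conventions; the frozen parameterisations are
documented feature-by-feature in `pprdetect.features.extract_features`.  The
choices that were genuinely open: temporal entropy uses a 10-bin amplitude
histogram; autocorrelation is the lag-1 normalized coefficient; roll-off /
roll-on sit at 95% / 5% of cumulative periodogram power; human-range energy
is the 0.6–2.5 Hz power fraction; spectral distance is the signed deviation
of the cumulative spectrum from its linear ramp; all spectra come from a
one-sided periodogram of the 500-sample window.  Degenerate inputs (constant
windows) return 0 for any feature whose definition would divide by zero,
never NaN.

Scaling to [0, 1] and PCA (smallest component count reaching ≥ 95% explained
variance) are fitted on each repetition's training fold only and applied
frozen to its test sets; test values are not clipped to [0, 1].  Zero-variance
features scale to 0.  The retained dimensionality is a data-dependent
outcome, not a constant.

## Cross-validation scheme

Defaults: 3000 non-PPR + 500 real PPR + 2500 synthetic PPR in training
(50/50), Test 1 = all remaining real windows, Test 2 = Test 1 plus synthetic
PPR topped up to 3000, recombined **only from Test 1's real PPR windows** —
the package's choice where the scheme's description is silent, because any
other parent pool would leak training windows into Test 2 (asserted via
recorded parent identifiers).  Sampling is without replacement within a
repetition and independent across repetitions, so a non-PPR window can serve
several repetitions' folds; this is the reading of "sub-sampling with
replacement" under which the scheme's published composition counts (e.g.
24,968 remaining non-PPR from 27,968) are exact.  Per-repetition randomness
comes from `numpy.random.default_rng([seed, repetition_index])`.

Two repetition modes exist: `random` (default, as above) and `holdout`,
where repetition *i* additionally keeps recording *i*'s windows out of the
training pools entirely — useful when repetitions should correspond to
held-out subjects.

## Models, metrics, statistics

KNN (Euclidean, majority vote, K ∈ {3, 5, 7, 9, 11, 13, 15}) scores a window
by its PPR-neighbour fraction; distance ties resolve by index order.  The
network is a single dense hidden layer (N ∈ {10, 20, 30, 40, 50}, ReLU) with
a probabilistic output, cross-entropy loss and Adam (learning rate 0.01,
≤ 200 epochs, early stopping on a 10% validation split with patience 20);
where the width grid is the design, the remaining training details are this
package's frozen choices, seeded for run-to-run reproducibility.

Confusion counts use a 0.5 score threshold; ACC, SENS and SPEC follow their
standard identities, which the evaluation object asserts exactly.  ROC curves
sweep the score threshold; AUC is the trapezoidal integral and equals the
normalized Mann–Whitney U statistic (tested).  "Global" ROC curves pool
scores across repetitions rather than averaging curves.  Single-class test
sets yield NaN with an explicit degenerate flag, never a silent 0.

Configuration comparison runs Shapiro per group and Levene across groups;
only when neither rejects at α = 0.05 does the one-way ANOVA on sensitivity
decide whether configurations share a population.  When a precondition fails
(including constant groups, where Shapiro is inapplicable) the report
abstains explicitly instead of switching tests silently.  The ANOVA path's
type-I error is calibration-tested at ≈ 5% under a simulated null.

## Problem sizes

The shipped experiment configuration — 10 synthetic recordings, 5
repetitions, K = 3 and N = 10 — was chosen as the smallest design that
exercises every pipeline stage at its default composition (3000/500/2500
folds) while leaving the across-repetition variance small enough for the
augmented-vs-unaugmented sensitivity comparison to be stable.  Larger grids
and repetition counts are a parameter change, not a code change.

## Known limitations

- The generator's single discharge morphology means the four positional cases
  differ only by placement; real PPR-type heterogeneity is absent.
- Performance numbers on synthetic data are not clinical performance claims;
  only within-pipeline contrasts transfer.
- The EDF writer is minimal (16-bit, 1-second records, integer sampling
  rates, annotations in a sidecar CSV rather than EDF+ annotation channels).
- `compare_configurations` abstains when ANOVA preconditions fail; no
  non-parametric fallback is wired in.
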