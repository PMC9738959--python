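# Methods

## Decoding model

The RC speller reduces symbol spelling to two nested problems.  The binary
problem — does one post-stimulus epoch contain a P300? — is solved by a
2-class learner whose output ρ is forced into [0, 1] so that scores from
different algorithms are commensurable.  The multi-class problem — which of
the n×m symbols was attended? — never sees a classifier: it is solved by
averaging ρ per stimulus code over sequences and taking the row and column
argmax.  This factorization assumes (a) the P300 is time-locked to the flash
and contained in the 0–667 ms window, (b) each sequence flashes every code
exactly once so codes are comparable within a sequence, and (c) epochs are
exchangeable across sequences, which additive stationary noise satisfies.

Ties in either argmax break to the lowest code index; this is deterministic
and only matters on degenerate (e.g., constant) score vectors.  The weighted
voting rule divides by the number of learners N rather than by Σw_i; since
the symbol decision is invariant to positive scaling of the score vector
(property-tested), the normalization cannot change a decision, and the rule
is implemented exactly as stated.

## Preprocessing

- Window: 0–667 ms post-onset; at fs = 240 Hz this is ⌊0.667·240⌋ = 160
  samples.  Fractional samples truncate.
- Filter: Butterworth bandpass of **total** order 8 (scipy second-order
  sections), edges 0.1 and 10 Hz.  Applied causally (`sosfilt`) by default
  because the speller is an online paradigm; a `zero_phase` flag switches to
  forward–backward filtering for offline analysis.  Measured response of
  the default design: gain 0.999 at 5 Hz, 2.9·10⁻⁴ at 60 Hz, −3 dB at the
  0.1/10 Hz edges.
- Decimation: plain subsampling by r = ⌊fs / (2 f_high)⌋ = 12, keeping
  ⌈160/12⌉ = 14 samples per channel; the 10 Hz low-pass is the anti-alias
  stage, so no second filter is applied.
- Features: channel-major concatenation, 64 × 14 = 896 values.  No artifact
  rejection, re-referencing, baseline correction, or channel selection is
  performed.

## Base learners

All four algorithms come from scikit-learn; the contribution of this
package is the contract around them, not the fits.

- `lda`, `logreg`: native posterior probabilities.
- `svm`: linear kernel; the margin is mapped to [0, 1] by Platt-style
  sigmoid calibration (`CalibratedClassifierCV`, 5-fold, single calibrated
  model).  The kernel choice is a default, not a tuned value.
- `pls`: regression of the {0, 1} label with 2 components (default, not
  tuned); the continuous prediction is clipped to [0, 1].

Voting weights are 5-fold stratified cross-validated accuracies rather than
resubstitution accuracy, which would saturate at 1.0 for flexible models
and make weighted voting indistinguishable from unweighted.  The 2:10 class
imbalance per sequence is left as-is (no reweighting or resampling).  All
stochastic fitting is seeded from the spec's `seed` field.

## Partitioning

Horizontal partitioning produces α single-sequence datasets (partition i =
the i-th sequence of every selection, β(n+m) epochs each); vertical
partitioning produces N consecutive blocks of whole selections (β/N·α(n+m)
epochs each when N | β).  Both are checked by property tests for pairwise
disjointness and exact union.  When N does not divide β the remainder
selections join the final block and a warning is issued; only the divisible
case has a canonical definition.  At decode time a horizontal ensemble pairs
learner i with sequence i in presentation order; if a selection has fewer
sequences than learners (truncated decoding), surplus learners are skipped
and the average divides by the number actually used.

## Synthetic data generator

The generator emulates the benchmark recording structure exactly: 6×6 grid,
α = 15 sequences per selection, each sequence an independent uniform
permutation of codes 1–12 with exactly two target flashes, 64 channels at
240 Hz, 667 ms epochs, β = 85 selections by default (15,300 epochs).
Target epochs add a Gaussian bump (amplitude 5 µV, peak 300 ms, SD 50 ms,
optional latency jitter) on a fixed "parietal" block — the quarter of the
montage just past its middle, channels 33–48 on 64 channels — and all
epochs receive additive Gaussian noise (SD 1 µV), white by default with an
AR(1) option.

What it does **not** emulate: real ERP component mixtures (N200, late
positivity), non-stationary and spatially correlated EEG background,
artifacts (blinks, EMG), overlapping epochs from the 175 ms inter-stimulus
interval of real spellers, or fatigue/attention drift.  Passing tests on
this generator therefore demonstrate correctness of the decoding machinery
and its statistical behavior under the stated noise model — not expected
accuracy on recorded EEG.  The amplitude/noise defaults are free parameters
chosen once so that single-classifier decoding lands in the high-90s
percent regime reported for well-performing subjects; they are not measured
values.  Inter-stimulus timing is not simulated because every consumer of
the data operates on epochs, never on the continuous stream.

## Numerical and design choices

- Scores are plain float64 averages; no tolerance is needed anywhere in the
  decision path, and the aggregation layer is verified against brute-force
  averaging to 1e-12.
- The epoch container stores raw (unfiltered) epochs; preprocessing is
  recomputed on demand, keeping the stored data format-agnostic to filter
  settings.
- `unknown` epoch labels are allowed so test-time data needs no ground
  truth; training refuses datasets containing them.
- Stream segmentation (cutting continuous recordings at stimulus-code
  rising edges) lives in the optional competition-file reader, which
  follows the 0–667 ms window literally; the reader is exercised only
  against a small synthetic stand-in .mat file written at test time.
- The CLI is a thin composition layer; the library API is the primary
  interface.

## Problem sizes

Tests and the acceptance script scale the study down where the full
benchmark size adds nothing: partition identities use the full β = 85 at
one channel (partition arithmetic is channel-independent); the
single-classifier recovery run uses β = 40 train / 20 test at the full
64-channel default; ensemble comparisons use β = 20/15; chance-level checks
use β = 36 test selections so the binomial interval around 1/36 is
informative.  These sizes are the package's own evaluation design.

## Known limitations

- Headline accuracies on the real benchmark recordings require the external
  competition files; the reader supports them but no claim is made that the
  preprocessing here matches the original entries flash-for-flash.
- PLS "probabilities" are clipped regression outputs, not calibrated
  posteriors; they are adequate for ranking codes but not for probability
  interpretation.
- Causal filtering shifts the P300 peak slightly later in the window; with
  the default 667 ms window the peak remains well inside it.
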