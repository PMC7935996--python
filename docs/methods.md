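# Methods

This note records the scientific and numerical choices behind
`eegdistract`: what each stage assumes, which parameters matter, what
the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Synthetic two-class EEG sessions

The generator (`signal_model`) emulates a within-subject distraction
experiment: 8 channels (10/20 labels, AFz reference, Fpz ground) at
512 Sa/s; sessions open with a 15 s baseline followed by 30 balanced,
randomly ordered trials of 2 s cue + 9.5 s task execution + 5 s relax.
Trial annotations mark the task-execution segment only, because that is
the labelled state.  The default composition — 17 subjects × 3 sessions
× 30 trials × 3 epochs/trial = 4590 epochs, half attentive — matches the
emulated study design.  Sliding 3 s windows with 1.5 s steps admit five
epochs per 9.5 s task; the default keeps the first three
(`epochs_per_trial=3`), and both counts are reachable through the
configuration since the emulated design reports three while the window
arithmetic allows five.

Background model: per-channel 1/f^β Gaussian noise (β = 1 by default,
amplitude capped below 0.1 Hz), plus one shared white source mixed
through a fixed random unit column — without that shared source the
channels would be independent and spatial filtering would have nothing
to exploit.  Background RMS is 10 µV per channel, a typical scalp-EEG
scale.

Class effect: a band-pass-filtered white-noise source (default
8–12 Hz — alpha, the band most associated with attentional state) added
to distracted-trial task segments through a fixed unit-norm topography
(posterior-weighted on the default montage).  A filtered-noise source,
not a sinusoid, so per-epoch variance fluctuates the way narrow-band EEG
power does.  `effect_amplitude` is the ratio of effect-source RMS to the
channel-average in-band background RMS; 1.0 is the default (a clearly
present but not dominant power change), 0 makes the classes
statistically identical, and ~3 ("high effect") drives the
Bayes-optimal accuracy of the pipeline to essentially 1, which is the
regime used for recovery checks.

What the generator does **not** emulate: real scalp volume conduction
(channel correlation comes from one shared source, not a head model),
non-stationarity across a session, eye/muscle artifacts (a sinusoidal
or blink-like component can be injected explicitly to exercise ICA),
subject-to-subject variability in topography or band, and any
event-locked (oddball ERP) structure.  Passing tests therefore show the
pipeline recovers band-limited, spatially fixed power differences under
realistic noise — not that it reaches any particular accuracy on real
patients.

## Preprocessing

* Broadband prefilter: Butterworth band-pass 0.5–48.5 Hz, design order
  4, applied with `sosfiltfilt` (zero phase; the effective order
  doubles).  "4th order" is the one-way design order, matching common
  tool semantics.  Signals shorter than the padding warm-up are
  rejected explicitly.
* Infomax-ICA: data are mean-removed and PCA-whitened in-package, then
  unmixed with the natural-gradient Infomax update (sigmoid
  nonlinearity; the extended variant is available and needed for
  sub-Gaussian sources such as sinusoidal artifacts).  Components are
  ordered by descending back-projected variance.  Requires
  n_samples ≥ 20 · n_channels² so the covariance is well conditioned.
  Non-convergence within `max_iter` returns the partial result flagged
  `converged=False` rather than raising.
* Artifact rejection is **never automatic**: `remove_components` takes
  explicit indices.  A helper flags candidates by excess kurtosis or
  correlation with a designated frontal channel, off by default,
  because the emulated study states no rejection criterion and
  inventing one silently would change the science.
* ICA is fit per recording (per subject-session), mirroring standard
  EEGLAB practice.
* Epoching: windows are half-open in samples, onsets quantized to the
  nearest sample; epochs per trial = floor((task − window)/step) + 1,
  optionally capped.  No window crosses a trial boundary.

## Filter bank

Chebyshev type II, design order 8, stopband attenuation 30 dB per band
(unstated in the emulated design; chosen for clean separation of 4 Hz
bands at 512 Sa/s and recorded in the `FilterBank` object).  The nominal
band edges are realized as the **one-way −3 dB (half-power) points**:
stopband edges are placed iteratively outside the band until the
realized half-power points land on the nominal edges (±0.02 Hz).  Two
zero-phase responses of adjacent bands then cross at gain 0.5 and sum to
≈1, making the 12-band tiling near-allpass over [0.5, 48.5] Hz
(band-sum reconstruction error ≈ 0.13 on 30 s broadband noise) while
center-frequency gain stays above −1 dB and the response two bands away
stays below −60 dB.  Placing the stopband edges directly on the band
edges instead leaves notches at every crossover (reconstruction error
0.39) and was rejected.  An unstable design at the requested order is
retried at halved order; the first band of the 9-band scheme (0–8 Hz)
is a low-pass, since a high-pass at DC is meaningless.

## CSP and features

Per band: per-epoch spatial covariance of the band-filtered,
mean-removed window, divided by its trace (scale invariance), averaged
within class.  The composite C₁+C₂ (plus a 1e-8 relative ridge against
rank deficiency) is whitened by its eigendecomposition; the whitened C₁
is diagonalized; rows of W are ordered by decreasing projected class-1
variance, so the paired class-2 eigenvalues are the complements to 1.
All n_channels components are retained per band — the feature count is
channels × bands (8/56/72/96) with no component sub-selection.

The scalar reducing each component's time course is the log of its
variance normalized by the per-band sum of component variances
(standard FBCSP practice; plain variance is available via
`log_variance=False`).  Because projected variance equals
diag(W Σ_epoch Wᵀ), the cached per-epoch band covariances are
sufficient statistics for both fitting and feature extraction, which is
what makes refitting CSP inside every cross-validation partition cheap.

## Spectral baselines

Welch periodogram, 1 s Hann segments, 50% overlap (estimator unstated
in the emulated design; chosen and logged).  Band power sums density
bins over half-open [lo, hi) intervals, so a tiling scheme partitions
the grid exactly and relative powers sum to 1 per channel.  For the
overlapping 9-band scheme the relative-power denominator is the total
power over [0, 40] Hz, not the sum of band powers, which would
double-count overlap regions and push "relative" values above 1.

## Classifiers and search spaces

Random-search domains follow the five-family hyperparameter table:
k-NN (11 distances, 3 weightings, k ∈ [1,5], Minkowski exponent
[0.5, 3]), SVM (box constraint and kernel scale log-uniform in
[1e-3, 1e3], Gaussian/linear/polynomial kernels, order 1–4), single
hidden layer network (relu/sigmoid/tanh, 25–200 neurons, weight decay
1e-4, fixed 300-epoch budget with early stopping on a 10% validation
split once the training set has ≥ 200 samples — below that a 10% split
is too small to be informative), Gaussian discriminants (six covariance
variants, gamma shrinkage toward the diagonal, delta
coefficient-thresholding), naive Bayes (normal, or kernel densities
with normal/box/Epanechnikov/triangle kernels and log-uniform width).
Conditional parameters are drawn only when active.  The Spearman
distance is realized as the correlation distance on per-sample ranks
(the same quantity, but vectorizable); Mahalanobis and standardized-
Euclidean parameters are estimated from the training partition.  k-NN
vote ties break toward the lowest class index (attentive).

knn/svm/ann are scikit-learn estimators; the discriminant variants and
kernel naive Bayes are implemented in-package because no installed
library exposes those exact families.

## Nested cross-validation and leakage guards

Tenfold outer, tenfold inner (inner count and the 50-draw default are
open parameters of the emulated design; both configurable).  Folds are
assigned to **trials**, shuffled per class and dealt round-robin from a
canonical (sorted) trial order, so the assignment is deterministic
under the seed and invariant to epoch order.  Two guards are treated as
part of the method, not options:

* epochs of one trial share a fold — they overlap by 1.5 s of signal,
  so splitting them across train/test would leak;
* everything supervised (CSP, any standardization) is refit inside each
  training partition.  The emulated design is silent on this, but
  fitting CSP on all data measurably inflates accuracy on label-free
  data, which the test suite demonstrates and forbids.

Feature standardization is applied only to PSD features for
scale-sensitive classifiers (knn/svm/ann).  CSP log-normalized-variance
features are already on a common scale by construction, and z-scoring
them was found to *suppress* exactly the informative dimensions
(high-effect k-NN accuracy 0.76 standardized vs 0.99 raw), so it is off
for FBCSP features by default and configurable.

Null-behaviour checks compare the mean outer accuracy with a 95%
binomial interval around 0.5 whose n is the number of **trials**, not
epochs: epochs from one trial share samples and are assigned to folds
together, so the trial is the independent unit and an epoch-level
interval would be anti-conservative.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: the full 4590-epoch composition for the
count identity; a 180-epoch (60-trial) high-effect set
(effect_amplitude = 3.0) for recovery and topography; a 750-epoch
(150-trial) null set (1 subject × 5 sessions × 30 trials × 5
epochs/trial) for chance-level checks, with 10 random-search draws.
These sizes keep a single-CPU run to a couple of minutes while leaving
the binomial interval around chance at about ±8 percentage points.

## Known limitations

* Headline accuracies from real recordings are not reproducible here:
  no recordings are distributed, and the generator makes no claim to
  physiological realism beyond band-limited power effects over 1/f
  noise.
* The EDF writer is minimal (16-bit, one-second records, whole-second
  recordings padded with zeros in the last record); it round-trips
  through MNE but does not implement EDF+ annotations — trials travel
  in a delimited sidecar instead.
* MATLAB-style discriminant regularization is approximated as
  covariance shrinkage toward the diagonal and linear-coefficient
  thresholding; the exact reference semantics differ in edge cases.
* Infomax convergence is assessed by weight change; on
  structure-free data the flag may stay false at tight tolerances even
  though the decomposition satisfies its reconstruction contract.
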