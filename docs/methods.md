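# Methods

## The hybrid step-detection model

Step counting on the wrist fails mostly through false positives: arm
movement produces step-like acceleration transients during washing,
typing, cooking.  The model therefore separates *when* from *how many*:

1. a classifier decides, per 10 s epoch, whether the wearer is walking
   (ground-truth definition: at least four steps in the epoch);
2. a two-state Hidden Markov Model smooths the predicted label sequence,
   exploiting the temporal coherence of gait (walking persists across
   adjacent epochs; isolated single-epoch flips are usually classifier
   noise);
3. steps are counted only inside smoothed walking epochs, by peak
   detection on a conditioned univariate signal.

Epochs are half-open intervals [start, start + 10 s); a trailing partial
epoch is discarded; an epoch is usable when at least half of its samples
are non-missing (non-wear is represented as a missing-sample mask, never
as zeros, so it cannot masquerade as stillness).

### Signal conditioning

The detection signal is the Euclidean norm of calibrated triaxial
acceleration minus 1 g (removing static gravity; not floored at zero),
clipped to ±2 g, then lowpass filtered at 5 Hz.  The filter is a
4th-order Butterworth applied forward–backward (zero phase) with
odd-symmetric edge extension: a flat passband and no phase shift of peak
positions, at the cost of a non-causal filter — acceptable for offline
processing.  The subtract-then-clip order follows the pipeline
definition.  Missing samples enter the filter as 0 g; epochs dominated by
missing data are invalid and contribute no counted peaks, so filter
artefacts at gap edges are inert.

### Epoch classifier

Two backends share one training recipe:

* **features** (default): 11 handcrafted per-epoch features — mean and SD
  of the gravity-removed magnitude, dominant frequency in 0.5–4 Hz and
  its fractional power, autocorrelation peak over 0.25–2 s lags, per-axis
  SDs and pairwise correlations — standardised and fed to logistic
  regression.  Windows are mean-pooled to ~25 Hz before feature
  extraction; every feature lives below 4 Hz, so pooling loses nothing
  and cuts cost by ~4× at 100 Hz input.
* **mlp_raw**: a compact one-hidden-layer network (32 tanh units) on the
  per-channel-standardised raw window mean-pooled to 10 Hz.  It learns
  rotation robustness from augmentation rather than from invariant
  features.

Training (both backends): minibatch Adam, learning rate 1e-4, batch 64,
at most 100 epochs, weighted cross-entropy.  Class weights are
target-share over empirical-share per class with a 10:90 walking:
non-walking target — the balance observed in 24 h free living — so a
training set with artificially abundant walking does not inflate the
walking prior.  Early stopping halts training when the validation loss
has not reached a new minimum for 5 consecutive epochs (ties count as not
decreasing) and restores the best-epoch parameters.  During training each
window is augmented by a rotation of uniform random angle about a uniform
random axis followed by a uniform random axis permutation; both are
isometries, so per-sample magnitudes are untouched.  The hard-label
threshold is 0.5 on the predicted walking probability.  Invalid epochs
receive probability NaN and label "unknown".

The trainer is a self-contained NumPy implementation (~100 lines); both
backends are small enough that CPU training takes seconds, and the whole
model is serialisable to a single JSON checkpoint.

### HMM smoother

States: non-walk (0) and walk (1).  Fitted supervised, by counting, from
validation-set predictions and their ground truth: emissions are
row-normalised confusion counts (true → predicted), transitions
row-normalised true-label bigrams, the prior the smoothed true-label
frequencies.  A pseudo-count of 1 on every cell keeps all probabilities
strictly positive even when a validation fold never exhibits some
transition.  Decoding is the Viterbi MAP path (posterior-marginal
decoding is available as an option); hard labels are required downstream
to gate counting.  Ties are broken toward non-walk — conservative
counting — and tie detection uses a 1e-9 log-space tolerance because
exactly tied path probabilities arise structurally from symmetric
observation runs and would otherwise resolve by floating-point noise.
Sequences are smoothed per contiguous run of valid epochs within one
recording, never across gaps or participants.

### Peak detection and tuning

A candidate peak is a strict local maximum of the conditioned signal.
Three screened heuristics follow: prominence (vertical distance from the
peak to its lowest bounding contour line) must reach the threshold; the
width measured at half prominence must not exceed the maximum (the width
criterion is an upper bound only — "maximum peak width" — with no lower
bound); finally, peaks closer than the minimum distance are pruned
greedily in descending height order (equal heights: earlier index wins).
Prominences and widths are independent of the thresholds, so they are
precomputed once per signal and every parameter combination is then a
cheap filter — this is what makes exhaustive grid tuning tractable.

Tuning minimises the mean over validation participants of the absolute
error between counted and true total steps, over an exhaustive grid
spanning prominence 0.1–1 g, distance 0.2–2 s, width 10 ms–1 s (default
steps 0.05 g / 0.1 s / 50 ms, ~4,500 cells, config-exposed).  Gating
during tuning uses ground-truth walking labels so peak parameters are not
confounded by classifier error.  Ties break toward higher prominence,
then longer distance, then smaller width (all conservative).  A peak on
an epoch boundary belongs to the epoch containing its sample index.

### Cross-validation harness

Participants are assigned to k = 10 folds of near-equal size (sizes
differ by at most one).  Grouping by participant and stratifying by epoch
label cannot both be exact, so stratification uses each participant's
walking-epoch fraction: participants are ordered by that fraction (seeded
jitter on ties) and dealt round-robin.  In each round the non-test folds
are split 80/20 at participant granularity into train and validation;
participant-disjointness of train/validation/test is asserted inside the
harness, not only in tests.  Each round trains the classifier, fits the
HMM on validation predictions, tunes peak parameters on validation
recordings, and evaluates end-to-end on the held-out fold.  The pooled
report aggregates per-participant totals across all test folds (each
participant is tested exactly once); the mean of within-fold MAPEs is
reported alongside, since both aggregations are defensible.

## Validation statistics

MAPE is the unweighted mean of per-participant absolute percent errors of
total steps (not pooled-count MAPE); mean bias is the signed analogue
(negative = undercounting), so |bias| ≤ MAPE always.  Spearman r uses
average ranks on ties and is undefined (NaN with a warning) for constant
vectors.  Bland–Altman reports the mean of pred − true differences and
mean ± 1.96 SD (ddof = 1) limits of agreement.  Annotator agreement is
the two-way random-effects, absolute-agreement, single-rater ICC(2,1);
two identical zero-variance raters return 1.0 by convention, flagged.
Classification metrics take walking as the positive class; precision is
NaN with a warning when no walking is predicted, and κ is the standard
chance-corrected agreement.

## Reference baselines

Both baselines operate on the unclassified signal, which is why they
overcount in free living relative to the hybrid model.

* **Threshold baseline** (acceleration-threshold family): one step per
  upward crossing of a 0.1 g threshold on the 5 Hz-lowpassed
  gravity-removed magnitude.
* **15 Hz peak-screening baseline** (Verisense family): recordings are
  resampled internally to 15 Hz (its constants are sample-count based);
  candidate peaks are strict maxima of a ±3-sample window with raw vector
  magnitude above 1.2 g; a candidate becomes a step only if its gap to
  the previous accepted peak is ≥ 5 samples, height similarity within
  0.5 g is required for gaps within the 15-sample periodicity band, and a
  continuity screen demands ≥ 4 candidates within a centred 3 s window
  (rejecting isolated impacts).

The exact constants used alongside the hybrid model in published
comparisons are not restated in the accompanying text, so the defaults
here follow the algorithms' own publications and community reference
code; every constant is a config field so alternative parameterisations
drop in without code changes.

## Cohort aggregation

QC excludes participants with < 72 h of wear, with any hour of day 0–23
never covered by a valid wear epoch, with failed device calibration
(an upstream tool's verdict, passed in as a boolean), or with mean
acceleration above 100 mg.  Missing minutes are imputed with the mean of
the same minute-of-day over all other days where that minute is valid;
minutes missing on every day become 0 and are flagged.  Daily steps are
the per-day sum over 1,440 minutes, summarised as the median over valid
days (even count: mean of the middle two).  One-minute peak cadence is
each day's maximum calendar-minute step count, summarised as the median
over valid days; a rolling-60 s maximum over raw step-event times is
provided as the switchable alternative operationalisation.

## The synthetic gait generator

Each walking bout is a train of raised-cosine acceleration pulses
(duration 0.25 s, one per step, centred on the step event) directed
orthogonally to gravity — an arm-swing proxy producing exactly one local
maximum per step within the 5 Hz detection bandwidth — superimposed on a
constant gravity vector plus white Gaussian arm noise.  Defaults: 100 Hz
sampling (the deployment recording rate), pulse amplitude 1.0 g (the
gravity-removed magnitude then peaks at √2 − 1 ≈ 0.41 g, inside the
plausible wrist range during walking and inside the prominence tuning
range), arm-noise SD 0.05 g.  Random cohort scenarios draw 2–4 bouts of
30–80 s at 80–120 steps/min separated by ≥ 15 s of rest over 6 min
recordings, giving a walking share of roughly 40–50% that the 10:90 class
weighting then rebalances, as in the free-living recipe.  Non-wear gaps
are missing-sample spans.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: non-gait arm transients (the hardest real
false-positive source), cadence drift within a bout, device clock drift
or calibration error, hip-worn placements, and the long sedentary
stretches of multiday wear.  Synthetic recovery results (MAPE ~2–3%,
κ ~0.95 on the 20-participant experiment) therefore verify the
*machinery* — labelling, smoothing, gating, tuning, aggregation — not
free-living accuracy, which for the published pipeline this mirrors was
an order of magnitude worse (double-digit MAPE).

## Numerical choices and edge cases

* Resampling is linear interpolation onto a uniform grid; output samples
  whose interpolation window touches a missing source sample stay
  missing; duration is preserved to within one sample period.
* Unparseable CSV rows become missing samples in place; non-monotone
  timestamps are an error, not silently sorted.
* The peak detector requires *strict* local maxima; exact two-sample
  plateaus (measure-zero for noisy signals, but constructible) yield no
  peak.
* `clip` before filtering bounds the conditioned signal up to small
  Butterworth overshoot.
* Even-count medians are the mean of the middle two throughout.
* All randomness flows from explicit integer seeds; a single global seed
  fans out to per-stage seeds by stable hashing (SHA-256, reduced below
  2^31), so stages re-run in isolation reproduce.

## Experiment sizes

The bundled experiments use 20 synthetic participants × 6 min at 100 Hz
for the cross-validated recovery run, 500 random signals (length ≤ 2,000)
for the peak-detector oracle check, 200 random cases (T ≤ 12) for the
Viterbi oracle check, and a 3 × 3 × 2 grid over 3 participants for the
tuning-argmin check — sizes chosen so the full verification runs in a few
minutes on a single CPU while leaving every code path exercised.

## Known limitations

* The published pipeline this design mirrors uses a self-supervised
  pretrained 18-layer 1-D ResNet as the epoch classifier; this package
  ships desk-trainable backends behind the same interface instead.
  Classifier quality on real free-living data is therefore not
  comparable; the pipeline contract (probabilistic epoch classifier →
  HMM → gated counting) is unchanged, and a stronger backend can be
  added behind the same `design/forward/grad` surface.
* Baseline constants await reconciliation against the original
  supplementary material (see config dataclasses).
* Native binary device formats (.cwa) and gravity calibration are out of
  scope; inputs are assumed calibrated, in g, as CSV.
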