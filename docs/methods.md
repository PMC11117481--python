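# Methods

`pdwear` re-implements, as an open and testable pipeline, the kind of
embedded analysis a waist-worn triaxial accelerometer performs when used to
monitor Parkinson's disease at home: continuous detection of gait and its
spatiotemporal parameters, of levodopa-induced dyskinesia periods, and of
freezing-of-gait (FOG) episodes, followed by the subject-level statistics
used to compare affected and unaffected patients.  Because no real patient
recordings ship with the package, a synthetic-data generator provides
labeled recordings with the statistical structure the detectors assume;
every stage is validated against that generator's ground truth.

## Signal conventions

The sensor is worn at the left anterior–superior iliac spine.  Axes:
x = anterior (forward), y = vertical (upward), z = lateral (left);
acceleration in g, full scale ±6 g, sampling rate 50 Hz.  Gravity (+1 g)
sits on the vertical axis at rest.

## Framing and features

Recordings are segmented into fixed 3.2 s frames overlapped by 50 %
(160 samples, hop 1.6 s).  The spectral estimator is the unwindowed
periodogram of the mean-removed frame: bin width 50/160 = 0.3125 Hz, band
membership by bin centre, half-open `[f_lo, f_hi)`.  Band energies are in
g² (mean power).

Axes are combined by **summing the three per-axis periodograms** of the
per-frame mean-removed axes.  This equals the total AC power of the vector
signal and is invariant under any static rotation of the device, so a
tilted belt does not change the features.  We deliberately do *not* take
the spectrum of the Euclidean magnitude: the magnitude is a rectifier, so
a single-axis oscillation at f Hz would appear at 2f with roughly half the
energy — a 2 Hz dyskinetic movement would land exactly on the edge of the
1–4 Hz band it is supposed to occupy.

Per frame the pipeline computes: band energies over [0.1, 3], [0.1, 10],
[1, 4] and [0, 20] Hz; per-axis mean absolute increments and standard
deviations; the three inter-axis Pearson correlations (defined as 0 for a
constant axis); dominant spectral peak frequency and magnitude (above
0.1 Hz); and spectral skewness/kurtosis of the normalized spectrum treated
as a distribution over frequency (0 for zero-power frames).

## Gait

A radial-basis-function SVM over the two band energies ([0.1, 3] and
[0.1, 10] Hz) classifies frames as gait / non-gait (γ = 0.5 on
standardized features — i.e. 1/(2·variance) — and C = 1).  Contiguous
positive frames merge into walking bouts; bouts shorter than 3 frames are
dropped.

Heel strikes are the minima of the 10 Hz low-pass-filtered (zero-phase,
4th-order Butterworth) anterior acceleration, with a minimum separation of
0.4 of the dominant heel-strike period (estimated from the 0.3–3 Hz
periodogram peak of the forward signal); closer candidates resolve to the
deeper minimum, and minima shallower than half the bout's median depth are
discarded (filter transients at bout edges).  One stride spans two
consecutive heel strikes and counts as **two steps** (the waist sensor
sees the strikes of one foot); the first two and last two strides of every
bout are excluded from analysis.

Per stride:

* **step length** from the inverted-pendulum model `2·sqrt(2·l·h − h²)`
  with leg length *l* and vertical centre-of-mass excursion *h*.  *h* is
  estimated by double integration of the mean-removed vertical
  acceleration over the stride, linear detrending of the displacement
  (bounds integration drift over ≤ 2 s), and `h = (max − min)/2`.
  Non-positive or out-of-range excursions mark the stride not-available.
* **stride speed** = 2·step_length / stride duration.
* **stride fluidity** = triaxial 0.1–10 Hz band energy of the stride's
  samples (band-energy units, g²).

Cadence is steps divided by walking-bout duration, times 60.  The duration
is taken as the span from first to last heel strike when at least two
exist: the SVM frame union over-pads the physical bout by up to one frame
per edge, which would bias cadence low by more than the 5 % recovery
tolerance.

Parameters are averaged (and their variance taken) per wall-clock minute;
minutes with fewer than 8 steps, zero values or missing values are
excluded as non-representative.

## Dyskinesia

A period is dyskinetic when the 1–4 Hz energy exceeds θ_high while the
0–20 Hz energy stays below θ_low, for at least 6 s.  The low-band gate
restricts the search to static periods (energetic voluntary movement
exceeds θ_low); frames classified as gait are never flagged.

Calibration (the device ships pre-calibrated; we calibrate on labeled
synthetic data): θ_high is the log-scale midpoint between the rest and
dyskinesia 1–4 Hz energy distributions; θ_low is the larger of the
per-state 95th percentiles of the 0–20 Hz energy over the static states
(rest, dyskinesia).  The maximum-per-state form matters: pooling the
states would let rest, the majority state, drag the percentile below the
energy of dyskinetic-but-static frames whenever dyskinesia is rare.

Persistence is measured at sample resolution: frames qualifying under the
dual rule select candidate spans (padded by one frame), and within each
span the triaxial 1–4 Hz amplitude envelope (per-axis Butterworth
band-pass + Hilbert magnitude, combined as the vector magnitude, smoothed
over 0.5 s) must stay at or above `sqrt(2·θ_high)` — the amplitude of the
sinusoid carrying exactly θ_high mean power — for ≥ 6 s (envelope dips
shorter than 0.3 s are bridged).  The frame grid alone (1.6 s hop) would
quantize the 6 s rule to 6.4 s or make it amplitude-dependent; the
envelope realizes the printed rule directly, and a burst-duration sweep in
0.1 s steps flags first at 6.0 s.

Flagged time is aggregated on a 10-minute grid anchored at the recording
start (the final partial window is scaled by its true length); the number
of *dyskinesia periods* is the number of positive 10-minute windows,
matching the device's 10-minute output granularity.

## Freezing of gait

An RBF SVM over the temporal and spectral features (increments, standard
deviations, correlations, dominant peak, spectral skewness/kurtosis, plus
the two locomotor band energies for context; 15 features total) classifies
frames as FOG / non-FOG.  Hyperparameters: γ = 'scale', C = 10, balanced
class weights — freezing frames are a tiny minority of any realistic
training corpus and an unweighted SVM simply ignores them.  Positive
frames merge into episodes with a one-hop gap tolerance; episodes are
searched only within 10 s of detected walking bouts (freezing is by
construct a gait phenomenon; the gate is configurable).

Per minute the pipeline reports the episode count (an episode counts in
the minute containing its start) and the seconds spent frozen (split
proportionally across minute boundaries).  Percent time with FOG divides
total FOG time by total walking time and is not-available when no walking
was detected.

## Subject-level statistics

Per subject, outcomes are totalled over all monitored days: number of
dyskinesia periods, time and percent time with dyskinesia; number of FOG
episodes, time and percent time with FOG (of walking time); and gait
means/variances over retained minutes.

* **Normalization**: min–max to [0, 1] per feature (constant features map
  to 0).  Inside cross-validation the bounds come from the training fold
  only and the held-out subject is clipped into [0, 1].
* **LOSO classification**: leave-one-subject-out logistic regression
  (ridge penalty C = 1, balanced class weights, own Newton/IRLS solver
  verified against scikit-learn).  Sensitivity, specificity, PPV, NPV and
  accuracy come from the pooled held-out probabilities at threshold 0.5.
  The reported **AUC is estimated leave-pair-out**: every
  (positive, negative) subject pair is scored by one model trained on the
  remaining n−2 subjects.  Pooling leave-one-out scores instead compares
  scores from different models and is pessimistically biased by O(1/n)
  under label exchange (with near-binary features the measured null mean
  was 0.35 rather than 0.5); leave-pair-out restores a calibrated null
  (≈ 0.49 measured) without touching the signal case.  The pooled
  concordance is still reported as `pooled_auc`.
* **Group comparison**: Mann–Whitney U (reported as min(U_a, U_b); exact
  p for n_a·n_b ≤ 400 without ties, tie-corrected normal approximation
  otherwise) with Cohen's d on the raw values (pooled SD); empirical CDFs
  for the primary outcomes.
* **Correlation**: Spearman's rank correlation.
* **Matching**: each case is paired with its most similar control by
  Euclidean distance on z-scored covariates (z-scoring gives every
  covariate equal weight; default covariates: age, disease duration, H&Y,
  MDS-UPDRS III, MoCA), greedy nearest-neighbour without replacement,
  hardest case first (largest minimum distance), with a standardized
  mean-difference balance table before/after.

## Synthetic data

The generator emulates a day at home: a semi-Markov scheduler alternates
rest (mean dwell 150 s), voluntary activity (90 s) and walking (45 s) with
exponential dwell times, over a gravity baseline with slow orientation
sway (< 0.05 Hz, below the 0.1 Hz feature edge) and a white noise floor
(0.008 g per axis).

* **Walking**: vertical sinusoid at step frequency whose amplitude encodes
  a centre-of-mass excursion of 0.025 m × speed scale (so step-length
  truth follows the same pendulum formula the estimator uses); a forward
  waveform with exactly one sharp minimum per stride at the planted
  heel-strike times (a phase-aligned harmonic keeps minima in place);
  0.6 s on/off taper (gait initiation).  Cadence is per-profile
  (60–140 steps/min) with 2 % per-bout jitter.
* **Dyskinesia**: inside rest segments only, Poisson-arriving episodes
  (≥ 10 s, mean ≈ 30 s) of band-limited 1–4 Hz movement — one coherent
  source per episode projected on the axes (vertical-dominant 0.06 g)
  plus small independent residue.  Coherence matters: involuntary
  writhing moves the trunk as a whole, and it is what makes the
  inter-axis correlation features informative.
* **FOG**: inside walking bouts, locomotion is replaced by a coherent
  3–8 Hz trembling source (~0.07 g per axis; the band is a modelling
  choice from the freeze-trembling literature) for 4–10 s; forward
  progression and heel strikes are suppressed.
* **Voluntary activity**: amplitude-modulated broadband (0.5–12 Hz) noise
  at ~0.12 g RMS per axis — energetic and non-periodic, the false-positive
  foil for both detectors.

Cohorts draw group-conditional covariates mirroring the usual clinical
picture (affected subjects: longer disease duration, higher MDS-UPDRS
III/IV, higher LEDD ≈ 1125 vs ≈ 600 mg), and per-group episode rates
(dyskinesia 2–5/h of static time; FOG 4–10/h of walking).  Defaults
follow the study protocol of 5 monitored days of 8 h; tests and the
acceptance checks use a single 8 h wearing day per subject — enough
exposure for every affected subject to express episodes at a fifth of the
compute.

What a green test does **not** establish: the generator contains no real
accelerometry — no upper-limb dyskinesia (invisible to a waist sensor),
no festination or shuffling gait, no postural transitions, no device
artifacts — so detector performance here bounds nothing about clinical
performance; it establishes that the pipeline's logic recovers the
structure it is designed for.

## Numerical choices and degenerate inputs

Trailing partial frames are dropped; a recording shorter than one frame
yields an empty frame set with a warning.  Zero-power frames give zero
spectral moments; zero-variance axes give zero correlation; zero pooled SD
gives not-available Cohen's d; constant inputs give not-available
Spearman's rho.  A bout with fewer than five heel strikes has no
contributing strides.  Percent FOG with zero walking time is
not-available.  All detectors and the pipeline are deterministic given the
configuration (seeds included); the synthetic generator is byte-identical
across runs for a fixed seed.

## Known limitations

The detectors are trained/calibrated on the generator's own world, so the
gait SVM's near-perfect frame accuracy reflects the separability the
generator creates, not clinical difficulty.  Dyskinesia amplitude below
the calibrated θ_high is invisible by construction.  The 3–8 Hz FOG
signature is an assumption.  Number-of-dyskinesia-periods follows the
10-minute-window convention; merged-span counting would give smaller
numbers.  The statistical layer applies no multiple-testing correction,
matching the study design it mirrors.
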