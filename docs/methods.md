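# Methods

`ambulate` implements a wrist-accelerometer ambulatory-status classifier —
a binary "walking/running vs not" decision for every 10-second epoch of a
30 Hz tri-axial signal — together with the analytical-validation framework
such an algorithm needs: two reference-label modalities, tag quality
control, participant-level splits and cross-validation, an operating
threshold tuned on daily aggregates, and participant-level bootstrap
uncertainty. Because real study data of this kind are proprietary, the
package ships a synthetic cohort simulator that reproduces the *statistical
structure* of the two study designs, and the whole pipeline is validated
end-to-end against the simulator's hidden ground truth.

## The classification model

Each epoch (300 samples) is summarized by 14 features in four families:

| family | features | definition |
|---|---|---|
| signal deviations (3) | `dev_x/y/z` | per-axis standard deviation, g |
| locomotor band energies (5) | `band_e1..5` | integrated Welch PSD of the gravity-removed vector magnitude over [0.6, 1.0), [1.0, 1.5), [1.5, 2.5), [2.5, 4.0), [4.0, 8.0) Hz, g² |
| signal percentiles (2) | `p95_mag`, `p95_jerk` | 95th percentile of gravity-removed magnitude (g) and of jerk magnitude \|Δmag\|·fs (g/s) |
| percentile differences (4) | `iqr_x/y/z/mag` | 75th − 25th percentile per axis and of magnitude, g |

The band edges bracket human cadence (both-feet step frequency,
typically 1.4–2.2 Hz) and its first harmonics; energy in these bands is
the physically meaningful signature of gait at the wrist. Gravity is
removed per epoch by subtracting the epoch-mean magnitude, which keeps
feature extraction a pure function of one epoch (no cross-epoch filter
state). The PSD uses Welch's method (Hann window, 150-sample segments,
50% overlap, density scaling); band energies are trapezoidal integrals
with the integrand clipped exactly at the band edges, so bands are
disjoint sub-intervals of [0, 15] Hz and their sum is bounded by total
signal power. Percentiles interpolate linearly between order statistics.

The classifier is a two-dense-layer network: 14 inputs → one hidden ReLU
layer (default width 32, configurable) → 2-way softmax. Training uses
Adam (learning rate 0.001), batch size 32, categorical cross-entropy, 10
passes over shuffled data, features z-scored by training-set statistics.
No class weighting is applied even though ambulatory prevalence under
device labels is ~10–15%. The network is implemented directly in NumPy —
at this size a deep-learning framework adds nothing, and the from-scratch
loop makes weights bit-reproducible under a fixed seed. Constant feature
columns are rejected at fit time (z-scoring would divide by zero).

### Operating threshold

The decision threshold on the ambulatory-class probability is *not* 0.5;
it is tuned to minimize the mean absolute percentage error (MAPE) of
**daily ambulatory time** (10 s × ambulatory epochs per calendar day, in
minutes). Participants in the training set are dealt round-robin (after a
seeded shuffle) into 5 folds; a fresh network is trained on each
4/5-complement and scores the held-out fold. Held-out scores pooled over
all folds are swept over a threshold grid (0.00–1.00, step 0.01);
predicted daily minutes per participant-day are compared with
device-reference daily minutes; the smallest threshold attaining the
minimum pooled MAPE is chosen. Participant-days with zero reference
minutes are excluded from MAPE (the percentage error is undefined) and
counted in the returned trace; they remain in MAE during evaluation.

## Reference labels and QC

* **Device labels** (pilot-style cohorts): an ankle reference device
  reports single-leg step counts in 10-second windows; a window with ≥ 3
  steps on the wearing foot is *ambulatory*, < 3 *nonambulatory*.
* **Self-report labels** (`pbhs_like` cohorts): on-watch tags with
  categories walk/run, still, other; still and other group to
  *nonambulatory*. An epoch is labeled only when its full 10 seconds lie
  inside tags of one effective class; partially covered epochs and epochs
  under conflicting simultaneous tags get no label. Full-coverage
  assignment avoids diluting labels at noisy tag boundaries.

Self-report tags pass a QC stratum first:

* `qc_minimal` removes gross user errors only — non-positive duration or
  duration > 24 h — and clips tags to watch wear time;
* `qc_high` is a stringent selection: additionally eliminates tags
  outside a [60 s, 4 h] duration window and tags overlapping another tag
  of the same participant, then trims a 10-second guard off both ends of
  every survivor (every retained tag is therefore truncated). The
  concrete rule set realizes "stringent" as duration sanity + overlap
  hygiene + boundary guards; the constants are module-level and
  deliberately simple.

A participant-day is *evaluable* when watch and reference wear intersect
for ≥ 8 hours within the calendar day (strict at the boundary: 7 h 59 m
fails, 8 h 00 m passes). Day boundaries are midnights of the simulation
clock; real deployments would substitute a local-timezone midnight.

## Splits

Always at the participant level — all of a person's epochs land on one
side, which keeps held-out metrics honest for within-person correlated
data. Pilot-style cohorts split 50-50 stratified by mean daily step
count: participants are sorted by activity, consecutive pairs send one
member to each side (random orientation), an odd cohort leaves the median
participant to a coin flip. Sorted pairing was chosen over greedy
balancing for simplicity and provable balance; on 70-participant
synthetic cohorts its between-half step-count difference sits in the left
tail of the random-split distribution. Self-report-style cohorts split uniformly
at random (no daily aggregates exist there).

## Evaluation statistics

Epoch level: confusion-matrix rates (ambulatory positive), AUC-ROC
(Mann-Whitney convention, ties half — computed via scikit-learn and
cross-checked in tests against a brute-force pairwise oracle), AUC-PRC
(trapezoidal over the precision-recall curve). Daily level: MAPE, median
APE, MAE, median AE, and R² (squared Pearson correlation of predicted vs
reference daily minutes) over evaluable days, plus modified Bland-Altman
pairs (reference, predicted − reference). Per-step-count sensitivity
reports the proportion of epochs predicted ambulatory for single-leg step
counts 0–11 (higher counts are too rare to bin).

Confidence intervals are percentile bootstrap (2.5th/97.5th) with 1000
resampling iterations at the participant level. For AUC the bootstrap
uses an exact pairwise decomposition: between-participant win/tie-count
matrices are precomputed once, so each resample's pooled AUC is a
quadratic form in resampling multiplicities — identical to recomputing
AUC on the pooled resampled epochs, at O(participants²) per iteration.
Resamples on which a statistic is undefined (single label class) are
redrawn, with a cap at 10× the iteration count.

Subgroup analysis computes AUC + CI per gender, age band (18–30 / 31–65 /
> 65, configurable) and race level, with missing demographics collected
into an `unknown` level; the subgroup-difference criterion is pairwise CI
overlap, deliberately not a formal test. The crossed train × test
evaluation trains the five canonical mixtures (qc_high, qc_minimal,
qc_high+pilot, qc_minimal+pilot, pilot) and reports the AUC range across
test sets per model vs the range across models per test set — the
comparison that shows whether test-label quality or training-data quality
dominates performance variability.

## The synthetic cohort simulator

The simulator generates what the two study designs would record, not
biomechanically realistic gait:

* **rest** — gravity vector plus white noise (σ = 0.03 g);
* **walking bouts** — cadence-locked sums of sinusoids at the
  participant's cadence and two harmonics, participant-specific
  amplitudes drawn once per participant from 0.1–0.5 g per axis
  (harmonics scaled ½ and ¼), plus the same noise floor; bout durations
  log-normal with a 3-minute median, placed without overlap on the
  10-second grid;
* **distractor segments** ("other" activity) — band-limited noise bursts
  (white noise σ = 0.15 g smoothed by a 3-tap moving average), so
  non-gait arm movement has broadband energy and classification is not
  trivially "any variance = walking".

Per participant-day, wear is one contiguous daytime block (non-wear is
the overnight complement, mirroring how devices are actually worn);
default wear duration is drawn once per participant from 8.5–11.5 h —
just above the 8-hour evaluability requirement, as in a compliant study
population. Daily walking time targets the participant's mean (log-normal
across participants, median 60 min/day, cut to 5–300) with ±10% daily
jitter. Reference step windows report single-leg steps =
round(cadence × 10 / 2) with small integer jitter inside bouts (the
reference device counts one foot, so per-window counts are half the
both-feet total), and occasional sub-threshold (< 3) incidental steps
outside bouts. Clean tags cover bouts exactly; "still" tags cover a
random 60% of rest runs ≥ 1 min.

Self-report noise channels (`pbhs_like` cohorts): Gaussian start/end
latencies (defaults 20 s / 30 s; the crossed-evaluation experiment uses
45 s / 90 s), 10% of tags missing, 2–3% stretched past a full day (the
user forgot to close the tag), 3% (experiment: 12%) recategorized. These
defaults were chosen to produce QC elimination/truncation rates of the
same order as real self-report tagging; an all-zero configuration is the
identity, which is what ties self-report labels exactly to the generative
truth in tests.

Randomness: one master seed; every participant (and participant-day, and
pipeline stage) derives its own substream by SHA-256 hashing of stable
identifiers, so cohorts are reproducible under participant reordering and
raw streams can be regenerated lazily — a cohort object stores steps,
tags, wear, demographics and per-epoch truth, while 30 Hz signal is
synthesized on demand one participant-day at a time (layout and signal
use independent substreams, so skipping synthesis changes nothing else).

### What passing tests do and do not show

The simulator's walking signature is strong and stationary; there is no
sensor drift, no posture change, no cycling/driving confound beyond the
distractor bursts, and demographics never influence the signal. Passing
the end-to-end validation therefore shows that the *pipeline machinery*
(featurization, labeling, QC, splitting, training, threshold search,
aggregation, bootstrap) is correct and recovers a recoverable signal —
near-ceiling AUC and near-zero MAPE on this easy cohort say nothing about
accuracy on real free-living data. The data-quality experiment likewise
reproduces the *qualitative* finding (test-label quality dominates AUC
variability over training-mixture choice), not any real-world magnitude.

## Problem sizes

The headline end-to-end validation uses 70 participants × 7 days
(≈ 1.8 M epochs, 35/35 split) — the pilot-study geometry. The crossed
train × test experiment uses 16 pilot-like + 16 pbhs-like participants ×
2 days per replicate: large enough that every training mixture learns the
right polarity (with ≤ 5 training participants the network can overfit
participant-specific gait amplitudes and even invert on held-out data —
a real small-cohort failure mode), small enough to replicate 10 times.
The bootstrap coverage check uses 500 replications of a 30-participant
Gaussian mean; the subgroup null check 20 cohorts of 12.

## Known limitations

* Feature formulas realize the stated family structure (deviations, five
  locomotor PSD bands, two 95th percentiles, four IQRs); other
  realizations of the same families would be equally admissible.
* The qc_high rule constants (duration window, guard width) are design
  choices exposed as module constants, validated only by their qualitative
  effect (stringent subset of qc_minimal, every survivor truncated).
* `R²` is squared Pearson correlation, not regression through the origin.
* The simulator's "other-activity" mix is a guess; no claim of realism.
* Probabilities are not calibrated; the threshold search compensates at
  the daily-aggregate level only.
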