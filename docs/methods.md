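# Methods

`afdas` re-implements, as a tested and reusable pipeline, the machinery for
predicting atrial fibrillation (AF) after acute ischaemic stroke from
continuous ECG monitoring (CEM): beat-stream cleaning, a 19-feature heart-
rate-variability (HRV) bank with hourly aggregation, ensemble classification
under patient-level nested cross-validation, Bayesian fusion of model
probabilities, an age/NIHSS benchmark score, and a DeLong/Fisher/bootstrap
evaluation layer.  Because stroke-unit monitoring cohorts with adjudicated
AF labels are not publicly shareable, the package ships a synthetic cohort
generator and exercises the whole analysis end-to-end on simulated data.

## The prediction problem

Paroxysmal AF is a major, frequently missed cause of ischaemic stroke.  In
the stroke unit every patient is monitored continuously for the first days;
the question the pipeline answers is whether the first hour of that
routinely collected beat-to-beat (RR) data, together with the patient's
age, can rank patients by their probability of newly detected AF — so that
prolonged cardiac monitoring can be targeted at those most likely to
benefit.  The classifier output is a risk score; operationally a decision
threshold is fixed at 90% specificity on derivation data and then frozen,
reflecting the clinical priority of enriching (not exhaustively screening)
the monitored population.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
cardiac electrophysiology:

* **Sinus RR series** come from an integral-pulse-frequency-modulation
  (IPFM) model: the instantaneous rate `(1 + m(t)) / mean_rr` is integrated
  on an 8 Hz grid and a beat fires at each integer crossing.  `m(t)` is the
  sum of a low-frequency (default 0.095 Hz) and a high-frequency (0.25 Hz)
  sinusoid plus `1/f^beta` broadband noise.  This gives controllable
  spectral ground truth (LF/HF band powers) and, through `beta`,
  controllable long-range correlation: for fractional noise the detrended-
  fluctuation exponent is approximately `(beta + 1) / 2`.
* **Ectopy**: randomly selected beats become premature supraventricular (S)
  or ventricular (V) extrasystoles — the beat is moved 35% of its preceding
  RR earlier and relabelled, preserving beat count and time order.  Onset
  counts are Poisson at configurable hourly rates.
* **AF episodes** (newly-detected-AF patients only) replace Poisson-placed
  spans of at least 30 s — the study definition of an AF event — with RR
  intervals drawn i.i.d. from a broad truncated normal (mean 600 ms,
  SD 150 ms).  Serial independence of RR inside an episode is the defining,
  testable property; no atrial model is attempted.  The replaced spans are
  returned as half-open alarm intervals, emulating bedside-monitor alarm
  metadata.
* **Short atrial runs** (< 30 s, no alarm) are inserted in AF-prone
  patients; inside runs, and inside AF episodes, the synthetic ECG omits
  the P wave and adds band-limited fibrillatory baseline noise.
* **Monitoring gaps**: Poisson gap onsets with lognormal lengths; gap
  windows are logged so bookkeeping is testable.
* **Clinical covariates** are drawn from parametric distributions whose
  group contrasts follow the direction and rough magnitude typical of
  stroke-unit cohorts: the AF group is older (default mean shift 8.3
  years, about 79 vs 71), has higher NIHSS and mRS and more heart
  failure; most other comorbidity rates differ little.
* **Synthetic ECG** (optional) places Gaussian P-QRS-T templates at beat
  times at 500 Hz, lead-II-like.  AF-prone patients additionally carry a
  persistently reduced P-wave amplitude (0.10 vs 0.15 mV group mean),
  emulating the atrial-myopathy morphology signal that a raw-ECG model can
  exploit even in sinus rhythm.

The AF-prone phenotype is controlled by explicit effect sizes, chosen once
as simulation defaults because quantitative between-group HRV effect sizes
are not available to copy: RMSSD-generating amplitudes x1.5, DFA alpha1 shift
-0.15, SVES rate x3, one un-alarmed atrial run per hour.  Inter-patient
heterogeneity is lognormal (log-SD 0.3 on short-term variability, 0.7 on
ectopy rates).  Every patient draws an independent RNG stream keyed by
(master seed, patient index), so cohorts are bit-reproducible and stable
under partial regeneration.

What the generator does **not** emulate — realistic 12-lead morphology,
circadian covariate dynamics, measurement artefacts beyond random O-labels
(1% of beats), label noise in the AF adjudication — bounds what passing
tests show: they demonstrate that the pipeline recovers planted structure
under its own assumptions, not that any cohort-level accuracy transfers to
real patients.

## Preprocessing rules

* Eligibility: at least 3 h of monitored time (beat coverage; pauses above
  30 s count as unmonitored) in *both* the core daytime window 09:00-18:00
  and the core nighttime window 21:00-06:00.  The requirement is applied
  over the whole record.
* AF excision: every beat inside an alarm interval extended by a 2.5-min
  buffer on each side is removed; buffered windows are merged and clipped
  at record boundaries.
* Beat filtering: beats labelled neither N, S nor V are removed entirely.
* Gap handling: a gap shorter than 3 s is bridged with
  `round(gap / local_median_RR) - 1` evenly spaced beats (the local median
  is taken over the ten valid RR intervals on each side); longer gaps
  become segment boundaries.
* 5-min segmentation: RR data are concatenated on a covered-time axis that
  excludes gap time and tiled greedily — a segment closes as soon as its
  covered span reaches 300 s, so every segment spans at least 300 s and
  residual tails are discarded.  Tiling across a long gap merges the
  pre-gap residual with post-gap data, minimising data loss.  Each segment
  is tagged with `floor(start / 3600 s)`, the hour index relative to
  recording start (the admission proxy).
* Raw ECG: 2560-sample (5.12 s at 500 Hz) non-overlapping windows anchored
  at record start, band-pass filtered with a zero-phase order-4 Butterworth
  at 0.5-50 Hz; a window is valid only with at least three beats, all
  N/S/V, outside buffered AF; 80 valid windows are sampled per patient
  without replacement (seeded).

Interpretations made where the rules admit alternatives (day/night
coverage summed over the whole record rather than per 24 h; tiling anchored
per contiguous run; merge-by-concatenation semantics) are deliberate and
fixed; the unit tests pin them.

## HRV feature bank

19 features per 5-min segment, averaged per clock hour and then across
hours in the analysis window (the final model uses hour 0 only):

| group | features | notes |
|---|---|---|
| time domain | mean_rr, median_rr, sdnn, cvnn, rmssd, pnn50 | SDNN uses the n-1 denominator; pNN50 threshold 50 ms |
| spectral | tp, lf, hf, lf_hf | tachogram cubic-resampled at 4 Hz; Welch, 256-sample Hann windows, 50% overlap; bands 0.003-0.4 / 0.04-0.15 / 0.15-0.4 Hz; units ms^2 |
| nonlinear | dfa_alpha1 (scales 4-16), dfa_alpha2 (16-64), sampen (m=2, r=0.2 SD), mse (mean SampEn over coarse scales 1-5, r fixed from scale 1), sd1, sd2, sd1_sd2 | no detrending before nonlinear metrics — standard detrending degrades their reliability on RR data |
| ectopy | s2n, v2n | extrasystole counts divided by normal-beat count |

Degenerate inputs: segments need >= 2 RR values for time-domain features
and >= 100 for DFA/entropy; a constant series has SampEn 0 by definition
and undefined DFA; a coarse-grained scale with no template matches
contributes nothing to the MSE mean.  Missing values propagate as NaN and
are median-imputed inside the model pipeline, with the medians fitted on
the training fold only.

## Models and validation protocol

* Outer validation: stratified shuffle split on patient identifiers, 5
  splits, 20% test size, one shared seed — every model kind sees identical
  test sets, which is what makes per-fold paired DeLong comparisons
  well-defined.
* Ensemble: a randomised search (default budget 8 draws) over gradient
  boosting, random forest and L2 logistic regression with documented
  hyperparameter grids, scored by 3-fold stratified inner ROC-AUC on the
  training fold, winner refit on the whole fold.  Class imbalance is
  handled by stratification plus class weighting where the family supports
  it.
* Raw-ECG model: a small numpy 1-D CNN (16 kernels of 128 samples, stride
  16, ReLU, global mean+max pooling, logistic head) trained with Adam at
  learning rate 0.001 for 20 epochs under binary cross-entropy — single
  threaded and bit-deterministic given its seed.  Patient-level risk is the
  mean probability over k randomly chosen 5.12-s segments; performance is
  non-decreasing in k up to a plateau.
* Fusion: the independent-odds product
  `P = p1 p2 / (p1 p2 + (1-p1)(1-p2))`, i.e. logit-additive combination of
  two conditionally independent evidence sources under a flat prior.
  Inputs are clipped to `[1e-6, 1-1e-6]` because the pair (0, 1) is a 0/0
  singularity.
* Benchmark: an age/NIHSS ranking score with *injected* coefficients.  The
  published score's weights are not bundled; simulation benchmarks use a
  clearly-labelled synthetic monotone stand-in
  (`synthetic_as5f_coefficients`).
* Attribution: permutation importance (mean ROC-AUC drop over 10 shuffles)
  with a sign taken from the rank correlation between feature and predicted
  risk, averaged across folds.

## Statistics

ROC-AUC is computed in the Mann-Whitney rank form with ties counted one
half.  Confidence intervals are percentile bootstrap over stratified
patient resamples (defaults: 200 per derivation fold, 1000 for validation
runs); stratified resampling guarantees both classes in every resample.
Model comparisons use the paired DeLong structural-component test per fold
and Fisher's method (`-2 sum ln p ~ chi2(2k)`) across folds; identical AUC
structure (zero variance of the difference) returns p = 1 by convention.
The clinical threshold is the smallest score with derivation specificity at
or above the 90% target (predicted-positive means score >= threshold),
frozen before validation.  Secondary metrics (sens/spec/PPV/NPV) are
compared by a paired t-test over 1000 bootstrap resamples, aggregated
across folds with Fisher's method; ratios undefined in a resample (0/0) are
dropped, and more than 10% undefined is an error.

## Problem sizes and numerical choices

End-to-end experiments simulate 400-patient derivation and 600-patient
validation cohorts at 6% newly-detected-AF prevalence with 75 minutes of
monitoring per patient — the final model consumes only the first hour, so
longer records would not change the measured quantities; the generator's
default of 72 h remains available for coverage and gap-bookkeeping tests.
The permutation null calibration (labels shuffled, features fixed) uses a
reduced search budget of 2 draws per fold, which leaves the pipeline
structure intact while keeping 50 replicates tractable on one CPU.
Probability clipping (1e-6), the p = 1 DeLong degenerate convention, the
>= orientation of predicted positives, and greedy 300-s tiling are the
package's tie-break choices where the protocol is silent.

## Known limitations

* The identity of the 19 HRV features is a registry choice: nine canonical
  features (TP, HF, LF, RMSSD, DFA, pNN50, MSE, SDNN, S2N) are fixed and
  the registry is filled to 19 with standard companions; a different
  registry changes the model inputs.
* The ensemble search space is a compact stand-in for a full AutoML search;
  the contract is the nested-CV protocol, not the searcher.
* The CNN is a deliberately small, generic architecture, not a re-creation
  of any published network; it demonstrates the raw-ECG branch at desk
  scale.
* Simulation AUCs reflect the planted effect sizes and must not be read as
  estimates of clinical performance; cohort-level accuracies cannot be
  reproduced without real patient data.
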