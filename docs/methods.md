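# Methods

## Problem and scope

The pipeline classifies driver drowsiness (binary: non-drowsy vs
drowsy) from inter-beat-interval (IBI) streams recorded during a 45-min
partially automated drive, comparing a consumer wristband (PPG-derived
IBIs, 64-Hz sampling, on-device peak filtering) against a medical-grade
ECG (RR intervals). Ground truth comes from trained observers rating
nine 5-min intervals on a 6-level scale, cross-checked against
video-detected micro-sleep events. The original recordings are not
deposited anywhere; a generative model of the cohort replaces them, so
that every claim the package makes is backed by code that runs.

## Ground truth

Ratings 1–3 are grouped as *non-drowsy*, 4–6 as *drowsy*. An eyelid
closure of at least 1 s is a micro-sleep event; its duration maps to a
level via the bins [1, 2) s → 4, [2, 4) s → 5, ≥ 4 s → 6. The 2–4 s bin
deliberately absorbs 3–4 s closures, which the rating scale's own
wording (level 5: 2–3 s, level 6: ≥ 4 s) leaves unassigned.

When an interval contains events, its rating is **replaced** by the
level derived from the longest closure in that interval. Replacement —
rather than taking the maximum of observer and event level — is the
only rule consistent with the published adjustment table, which
contains one downward correction (6 → 4). Events are assigned to the
5-min interval containing their onset (the onset marks the lapse);
intervals are 0-based and half-open, [300·k, 300·(k+1)) s. Intervals
with events but no rating gain a new label; intervals with neither are
absent. The published narrative mentions 23 adjusted ratings while the
adjustment table sums to 21 changes plus 2 new ratings; the
implementation follows the table, whose arithmetic exactly reproduces
the published class counts (212/32 → 196/50, 246 labels total).

Rater reliability: percent agreement and Cohen's κ = (p_o − p_e)/(1 −
p_e) with chance agreement p_e from the two raters' marginal level
frequencies. The published agreement fraction (191/244 = 78.28%) is
reproducible from counts alone and is checked; the published κ of 0.69
depends on the full joint rater distribution, which is not published,
so κ is verified against scikit-learn on constructed data instead.

## Feature extraction

Windows of 300 s slide over the recording with a configurable step
(default 2 s); a window covers beats with time in [start, start+300)
and is dropped if it holds fewer than 4 intervals. Each retained window
is labeled by the interval containing its **end** (its last covered
instant, so [0, 300) belongs to interval 0 and [298, 598) to interval
1): the most recent drowsiness state is what a detector would act on.
Windows ending in an unlabeled interval are dropped.

Per window, 26 features in a fixed order:

* **Time domain (13).** meanRR/maxRR/minRR/rangeRR in ms; SDNN = sample
  (n−1) standard deviation; instantaneous heart rate HR_i = 60000/RR_i
  gives maxHR/minHR/meanHR/SDHR (so maxHR·minRR = 60000 exactly); RMSSD;
  NN50 counts successive differences strictly greater than 50 ms;
  pNN50 = 100·NN50/(n−1). SDANNIndex classically averages 5-min-segment
  SDs over a long recording and degenerates inside a single 5-min
  window; it is defined as the window's SDNN so the feature stays
  well-defined (a near-duplicate of SDNN, by construction).
* **Frequency domain (10).** The Lomb–Scargle periodogram of the
  mean-centred RR series is evaluated on a grid of 0.002–0.4 Hz at
  0.002 Hz spacing (resolving the 0.04 Hz VLF/LF edge) directly on the
  uneven beat times — no interpolation or resampling, and wristband and
  ECG series are processed identically. The raw periodogram is rescaled
  so its trapezoidal integral over the grid equals the sample variance
  of the window's intervals; band powers VLF (0–0.04 Hz), LF
  (0.04–0.15 Hz) and HF (0.15–0.4 Hz) are trapezoidal integrals in ms²,
  Totalpower is their sum, and the derived quantities are pVLF/pLF/pHF,
  LFnorm/HFnorm (relative to Totalpower − VLF) and LF/HF. The exact
  normalisation convention is a declared choice; every ratio-type
  feature is invariant to it. A window with zero HF power has an
  undefined LF/HF and is dropped with a warning.
* **Nonlinear (3).** Poincaré SD1² = var(ΔRR)/2 and SD2² = 2·var(RR) −
  SD1², both with population variances so the identity holds exactly;
  SD1/SD2 is undefined (window dropped) when SD2 = 0.

No artifact correction or beat filtering is applied: the wristband
already filters false peaks on-device, and the raw streams are used.

## Balancing, selection, evaluation

The drowsy class is the minority. Inside every training fold — never on
test rows — SMOTE oversamples the minority to exact parity: x_new = x +
u·(x_nn − x) with u ~ U(0,1) and x_nn one of the k = 5 nearest minority
neighbours (Euclidean; k is clipped below the minority count when
needed). The oversampling amount (parity) and k are declared defaults.

CFS then scores feature subsets by merit = k·mean|r_cf| / sqrt(k +
k(k−1)·mean|r_ff|), with Pearson feature–feature correlations and
point-biserial feature–class correlations on the numeric features
directly (no discretisation). A forward best-first search expands the
open subset of highest merit by single-feature additions and stops
after 5 consecutive expansions without improving the global best; ties
break lexicographically on feature names, making the search
deterministic. On up to 12 features the search provably (by test)
matches exhaustive merit maximisation.

Two protocols: **UDT** (user-dependent), stratified 10-fold CV over
instances ignoring subject identity — stratification shuffles within
class and deals round-robin, keeping per-fold class proportions within
one instance of the global ones; and **UIT** (user-independent),
leave-one-subject-out. Metrics per fold, averaged arithmetically over
folds: accuracy (%), and F = 2TP/(2TP+FP+FN) per class — F1 with
non-drowsy positive, F2 with drowsy positive; F is 0 with a warning
when its denominator vanishes. Per-fold averaging (rather than pooling)
follows the protocol description of averaging across iterations.

Classifier adapters: 1-NN (brute-force Euclidean, first-index
tie-break) and the decision stump (exhaustive midpoint scan minimising
training error, ties to lower feature index then threshold) are native;
naive Bayes (Gaussian), SVM (polynomial kernel, C = 1, standardised
inputs), random forest (100 trees), random tree and MLP ((n_features +
n_classes)/2 hidden units, SGD with learning rate 0.3, momentum 0.2,
batch 100) wrap scikit-learn at otherwise-default, untuned settings.
The original study also ran a K2 Bayesian network and a Weka-style
decision table; no equivalent exists in the adapter library and they
are not provided — unknown names raise an error listing the roster.

## Synthetic cohort model

Each subject draws a resting mean RR offset (Gaussian, SD 40 ms) and an
HRV magnitude scale (log-normal, σ = 0.3): the two channels of
inter-driver variance. A latent trajectory over the nine intervals is a
rounded, clipped random walk around a population mean path that rises
to about minute 30, dips over minutes 30–40 and rises again at the end.

The ECG-grade series is generated beat by beat: RR = baseline + offset
+ state shift + LF tone (0.10 Hz) + HF tone (0.25 Hz) + Gaussian noise,
with beat times as cumulative sums. Drowsiness is encoded as
parasympathetic dominance with both a mild per-level gradient (10 ms
meanRR, 4 ms HF amplitude per level) and a distinct mode switch at the
drowsy boundary (default +25 ms meanRR, +15 ms HF amplitude for levels
≥ 4; the LF amplitude declines with level). The mode switch reflects
the autonomic account of drowsiness as a state change and keeps the
binary classes separated rather than merely ordered; effect magnitudes
are free parameters with no published values behind them. The
wristband-grade series drops interior beats independently (p = 0.1,
merging adjacent intervals), quantises beat times to the 1/64-s PPG
sampling grid and adds 4-ms timing jitter — so the wristband always
yields fewer usable beats and windows than the ECG. Two raters report
the true level plus independent rounded Gaussian noise (SD 0.5 levels,
clipped to 1–6; the joint rating is the rounded rater mean), and
micro-sleep events follow a Poisson process (1.5/min) in intervals with
true level ≥ 4, with closure durations 1 + Exp(0.8·(level−3)) s so all
three duration bins occur. All randomness derives from one master seed
through per-subject substreams.

What the generator does **not** emulate: real PPG motion artifacts and
their nonstationary burst structure, respiratory coupling and
nonstationary LF/HF dynamics within an interval, circadian effects, and
any systematic rater bias. Passing tests therefore demonstrate that the
pipeline recovers structure the generator encodes — not that the
published accuracy figures transfer to real recordings, which are
computed on data this package cannot access and are deliberately not
treated as numeric targets.

## Parameter-recovery study conditions

The recovery experiments use 10 subjects and **non-overlapping** 300-s
windows (step = 300 s, nine windows per subject and device). With the
default 2-s step, adjacent windows share over 99% of their beats, so
instance-level cross-validation scores near-perfectly through temporal
near-duplicates regardless of signal content; independence of instances
is required for the chance-level control to mean anything. The
*separated* condition strengthens the drowsy mode switch (+60 ms
meanRR, +30 ms HF) and uses noise-free raters, so the class signal is
fully present in the features; the *null* condition is identical except
that all state-dependent terms and both inter-driver variance channels
are zero, making every window's features exchangeable (subject-specific
offsets are removed because, with only 10 subjects, a nearest-neighbour
classifier can otherwise recover per-subject label priors from the
offset alone and sit above chance without any state information).
Under the separated condition, user-dependent 1-NN accuracy exceeds
90% and user-dependent exceeds user-independent accuracy; under the
null, accuracy averaged over 10 seeds sits near 50%. A small upward
bias above exact chance (a few percentage points) is expected at this
sample size: with ~9 minority training instances per fold, SMOTE's
interpolated minority points cover the feature space less evenly than
the genuine majority sample, tilting nearest-neighbour votes toward
the majority class; the bias vanishes as instance counts grow.

## Numerical conventions

Sample (n−1) variance for SDNN/SDHR and the spectral normalisation;
population variance inside the Poincaré identities. NN50 uses strict
inequality. IBI series validate intervals against beat-time differences
to 1 ms and reject non-positive intervals or non-increasing times;
beat gaps over 3 s are flagged as dropouts but never filled. Feature
tables round-trip through CSV at 12 significant digits. All stochastic
operations accept explicit seeds; fold assignment, SMOTE draws, search
tie-breaks and classifier seeds are deterministic given the seed.
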