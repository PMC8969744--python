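# Methods

This package reproduces, on synthetic data, the complete sensor-space
analysis of a two-state auditory odd-ball EEG experiment: a baseline
state (PRE) and a hypnotic-deafness state (HYP), each stimulated with
series of five sounds whose fifth element is either identical
("standard") or different ("deviant").  The subject recording the
analysis was designed for is not publicly deposited, so the package
ships a synthetic-EEG generator that emulates the statistical structure
the analyses assume; every stage of the pipeline is validated against
that generator's ground truth.

## Paradigm

Sounds are 50-ms triples of sinusoids (sound A: 350/700/1400 Hz; sound
B: 500/1000/2000 Hz) with 7-ms linear rise/fall ramps, peak-normalized;
loudness calibration is out of scope (a dB SPL figure has no meaning
for a digital file).  Series present five sounds at a 150-ms onset
asynchrony; blocks contain 78 series, 67% standard / 33% deviant
(`round(0.33 * 78) = 26` deviants, rounding half away from zero), in
uniformly shuffled order — no constraint on consecutive deviants is
imposed because none is part of the design.  Consecutive series are
separated by a silent interval drawn uniformly from the discrete grid
1.350–1.650 s in 50-ms steps, measured from the end of the fifth sound.
All randomization is driven by explicit seeds; identical seeds give
byte-identical schedules.

## Synthetic EEG

The generator renders continuous multichannel EEG at 250 Hz on a
sunflower-disc montage (default 64 sensors; analyses parameterize all
sensor groups, so no exact layout identity matters).  Sensor groups are
anterior / fronto-central / centro-posterior thirds of the layout by the
anterior–posterior coordinate.

**Evoked components.**  Each component is a Hanning bump spanning its
latency window, scaled so its *mean* over the window equals the
configured amplitude — the injected number is therefore exactly what a
window-averaged ERP measurement recovers (window averages use a
half-open [lo, hi) sample convention so windows are commensurate with
kernels).  P1 (68–116 ms post-onset) follows every sound; MMN
(140–192 ms), P3a (280–340 ms) and P3b (400–800 ms) are time-locked to
the fifth sound with per-(state, stimulus) amplitudes.  Topographies are
zero-mean across the montage (so average referencing is exactly neutral
for injected effects), with the counterweight of each deviant-related
component placed on the anterior group and vice versa: sharing ROI
sensors between one component and another component's counterweight
would let the band-pass filter's temporal smearing bias neighbouring
measurement windows.

**Background noise.**  Three ingredients, all 1/f^α with α = 1 unless
configured otherwise:

1. sensor-private 1/f noise;
2. spatially shared noise — eight 1/f sources mixed into all sensors
   through a random unit-norm mixing matrix (`spatial_mixing` sets the
   shared variance fraction, default 0.6), standing in for volume
   conduction;
3. component-topography-aligned noise (`topo_noise_std`): 1/f activity
   projected through each component's own topography, i.e. ongoing
   activity of the same generators that produce the evoked responses.
   Without it, multivariate decoding is strictly more sensitive than ROI
   averaging (spatially independent noise averages away across sensors),
   which real recordings do not show; with it, an effect can be solidly
   significant in the trial-averaged ERP yet near the decoding
   threshold — the regime the original analyses live in.

An alpha-band (10 Hz) oscillation is generated as *stochastic
narrowband noise* (Gaussian-bump spectral shaping, ~15% relative
bandwidth), not as a deterministic sinusoid: the inter-series interval
grid steps by 50 ms, exactly half the alpha period, so a phase-locked
sinusoid would be sampled at a discrete set of phases by the epoching
and masquerade as a condition effect.  This was caught by the null
calibration and is a good illustration of why the generator exists.

**Default noise level.**  `noise_std = 7` µV broadband plus
`topo_noise_std = 1` µV and a 1-µV alpha component yields, after the
0.5–10 Hz ERP filter, single-trial ROI window-amplitude standard
deviations of roughly 0.7 µV (400-ms window) to 1.8 µV (60-ms window) —
the variability of a clean, high-density single-subject recording.
This is the package's definition of "moderate noise" for the reference
study; it is a generator property, configurable per run.

**Fixtures.**  Planted artifacts are step waveforms of configurable
peak-to-peak amplitude (default 1000 µV, ten times the rejection
threshold) addressed by explicit channel/epoch indices.  Sensor-pair
coupling adds a delayed, scaled copy of a source channel onto a target;
lags are whole samples.

## Preprocessing

Zero-phase (forward–backward) 4th-order Butterworth band-pass — 0.5–10
Hz for ERP/decoding, 0.5–45 Hz for spectral/connectivity — with 50 and
100 Hz notch filters (Q = 30); the DC component is removed first.
Epochs span −200..+1400 ms around the first sound (400 samples at 250
Hz); realignment to the fifth sound (−800..+800 ms) is a pure time-axis
relabelling at the 150-ms SOA.  Baselines: the 800 ms before the fifth
sound (ERP mode) or the 200 ms before the first sound (spectral mode).

Automated rejection, in order: (1) channels whose peak-to-peak exceeds
100 µV in more than 50% of epochs; (2) channels whose mean variance
z-scores above 4 across surviving channels — run twice, statistics
recomputed after each pass; (3) epochs whose peak-to-peak exceeds 100 µV
on more than 10% of surviving channels; (4) rejected channels
interpolated by distance-weighted averages of adjacent kept sensors.
The recording passes if ≥70% of channels *and* ≥70% of epochs survive.
Note an intrinsic property of the z-rule: with n channels the largest
attainable single-outlier z is (n−1)/√n, so the rule only bites on
dense montages (it cannot fire for one bad channel among 16 — which is
faithful to its intended dense-net setting).

## ERP statistics

ROI trial series are plain means over the ROI sensors.  The
mass-univariate two-way ANOVA (factors STATE and STIMULUS, between
trials) uses type-II sums of squares computed by model comparison
(RSS via QR decomposition, vectorized over time points); on balanced
designs this reduces to the classical decomposition, and it matches
statsmodels' `anova_lm(typ=2)` to 1e-9 (asserted in tests).
Benjamini–Hochberg FDR is applied across time points separately per
factor (the correction family is recorded in the output).  Component
amplitudes are window averages over the predefined windows (P1
−532..−484 ms, MMN 140..192 ms, P3a 280..340 ms, P3b 400..800 ms, all
relative to the fifth sound).  Post hoc deviant-vs-standard contrasts
are Welch t-tests (the fractional degrees of freedom in the reference
results imply unequal-variance tests) with Cohen's d on the pooled SD,
FDR-corrected over the per-state family; the sign convention is deviant
minus standard.  Bayes factors are JZS (Cauchy prior, scale √2/2) by
numerical integration of the Rouder marginal-likelihood ratio;
pingouin's implementation serves as an independent oracle in the tests.
The interaction-term Bayes factor is approximated by BIC comparison of
the full versus no-interaction linear model — a deliberate,
order-of-magnitude stand-in for full Bayesian model averaging.

## Decoding

At each time sample, the feature vector is the set of channel
amplitudes.  Features are standardized with training-trial statistics; a
linear-kernel SVM (C = 1, fixed — tuning would add an unspecified
nested CV) with inverse-class-frequency weights is fitted, and a Platt
sigmoid is fitted to the training decision values.  Within-condition
performance uses 7-fold stratified cross-validation, pooling held-out
probabilities before computing the AUC; cross-condition transfer trains
on all trials of one state and tests on all of the other.  Temporal
generalization uses 5-fold stratified CV, evaluating each training-time
model at every test time.

Significance: trial labels are shuffled and the whole CV decoding
repeated; p(t) = #{permutation AUC ≥ true AUC} / (n_perm + 1), floored
at 1/(n_perm + 1) (the counting formula would otherwise emit an
unusable p = 0), then BH-FDR across time.  Permutation repeats skip the
Platt fit and pool raw decision values: the sigmoid is strictly
monotone and AUC rank-based, so the permuted AUCs are identical while
each fit is cheaper.  Cross-condition nulls, where used, shuffle
training labels with full retraining.

A property worth knowing: cross-validated AUC under the null has
noticeably heavier tails than the binomial intuition suggests (folds
share training data), with a null SD near 0.10 at ~80 trials.  The
permutation procedure is calibrated precisely because it repeats the
identical CV; fixed thresholds on raw AUC values are not.

**Desk-scale inference grid.**  The reference study decodes 80-ms-spaced
samples of the −0.2..0.8 s window (13 time points) with 100
permutations.  With the 1/101 p-floor and BH over 13 points, at least
three floor-level p-values are needed for any significance.  A
sustained 400-ms effect covers 4–5 grid points and clears this bar; a
transient 60-ms effect covers 1–2 and cannot — which is exactly how
the published asymmetry (significant decoding in the baseline state
only, despite a *larger*-amplitude transient component in the other
state) becomes reproducible at reduced permutation counts.  These sizes
are configuration, not constants.

## Pseudo-resting-state markers

Markers are computed per sensor and per epoch on the 800-ms window
before the fifth sound.  Normalized PSD uses a single full-window Hann
taper (the window is too short for multi-segment averaging at delta
frequencies); band power is the sum of PSD bins in [lo, hi) divided by
total power in [1, 45), so the five canonical bands (δ 1–4, θ 4–8,
α 8–12, β 12–30, γ 30–45 Hz) tile the total and sum to one exactly.

wSMI: each channel is transformed into rank-order symbols of k = 3
samples spaced τ apart (6 possible patterns; ties broken by temporal
order).  For each sensor pair the joint symbol distribution within the
epoch gives a weighted mutual information, with zero weight on
identical and sign-opposite symbol pairs (suppressing common-source and
volume-conduction artifacts) and normalization by log k! (bounding the
value by 1).  τ defaults per band to 64/32/16 ms (16/8/4 samples at 250
Hz) for δ/θ/α, so the symbol span targets each band's period; both τ
and the band list are configuration.  Per-sensor topographies take the
median connectivity of each sensor to all others.  Two estimator
properties to keep in mind: the plug-in MI of independent channels
carries a positive bias of roughly (#weighted cells − 1)/(2 m log k!)
(~0.03 for 200-sample windows), and a *near-identical* lagged copy is
actively suppressed by the weights — wSMI responds to lagged,
partially transformed dependence, not to duplication.

Cluster inference: per-sensor Welch t-maps are thresholded at the
two-sided p < 0.05 t-quantile (configurable), suprathreshold sensors of
equal sign are grouped by montage adjacency, and each cluster's mass
Σ|t| is compared with the null distribution of the maximal cluster
mass over condition-label shuffles (10,000 by default; reduced in
tests).  Cluster p-values use add-one smoothing, (1 + #{max ≥
mass})/(n_perm + 1).  Sign-separated clustering and the max-statistic
convention follow standard topographic-cluster practice.  Per-sensor
Bayes-factor maps reuse the JZS engine.

## Reference study and validation strategy

`oddball.experiments.reference_config()` pins the published design (two
states × two blocks × 78 series, 33% deviants) with the reported
state-specific late effects: P3b deviant response 1.36 µV in PRE only,
P3a 2.23 µV in HYP only, no mismatch-response difference between
states.  Validation then has two deliberately separated layers:

* **Amplitude recovery** is measured on raw (unfiltered) epochs at low
  generator noise, where the generator's contract is exact and the
  pooled deviant-minus-standard window average converges to the
  injected value at 1/√n.  The ERP band-pass attenuates window averages
  (the 0.5-Hz high-pass turns an isolated slow bump into a bump plus a
  broad shallow surround; up to ~35% for the 400-ms component after
  baselining) — that is a property of the filter applied to this
  signal shape, shared by any pipeline using it, not a generator error.

* **Pattern recovery** runs the full filtered pipeline at the default
  moderate noise and checks the qualitative result pattern per seed:
  STATE × STIMULUS interaction for both late components, post hoc
  contrasts significant in the expected state only, FDR-significant
  decoding in PRE only, and a late sustained ("square")
  temporal-generalization block in PRE only.  The expected pass rate is
  ≥ 8/10 seeds; individual failures are dominated by the ~5% false
  positives the null contrasts are designed to emit.

Null calibration of each inferential device (ANOVA-FDR fraction,
permutation-decoding mask, cluster false-positive rate) is checked
under the global null at reduced sizes; sizes appear in
`oddball.experiments` and `scripts/acceptance.py`.

## What the generator does and does not emulate

Emulated: event-locked evoked structure with condition-dependent
amplitudes, 1/f spectra, band oscillations, spatial correlation,
generator-aligned ongoing activity, high-amplitude artifacts, lagged
inter-sensor coupling, the exact paradigm timing.  Not emulated:
biophysical head geometry and realistic smooth topographies, eye-blink
and muscle artifact morphology (steps suffice for threshold rules),
non-stationarities such as electrode drying, sound-identity-specific
(A vs. B) responses, and any source-space structure.  Passing tests
therefore demonstrate the *analysis code* is correct and calibrated
under the assumed statistical structure — not that the scientific
conclusions would survive on another subject's data.

## Known limitations

* The interaction Bayes factor is a BIC approximation, not averaged
  over a model space.
* Channel interpolation is distance-weighted averaging over the
  synthetic adjacency, appropriate for the disc layout but cruder than
  spherical splines on a real head.
* Normalized PSD from a single 800-ms window has 1.25-Hz resolution;
  delta-band estimates rest on two to three bins.
* The variance z-score rejection rule is ineffective on sparse
  montages by construction (see above).
* The permutation-decoding grid trades temporal resolution for honest
  permutation counts at desk scale; users with more compute should
  raise `n_perm_decoding` and lower `decoding_decim` together.
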