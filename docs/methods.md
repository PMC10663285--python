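# Methods

`reachdecode` implements a time-resolved multivariate decoding analysis of
reach-to-grasp EEG: binary classification of hand action (grasp vs. touch)
and reaching direction (left vs. right handle) from low-frequency scalp
potentials, in three configurations — within-hand cross-validation, normal
cross-hand transfer, and mirror cross-hand transfer — under two class
labelings of direction, extrinsic (object-centered) and intrinsic
(limb-centered). This note describes the models, the parameters that
matter, the synthetic data the pipeline is validated on, and the numerical
choices made where the design was open.

## Task model

The experiment crosses reaching direction D ∈ {L, R} (target handle),
action A ∈ {G, T}, and hand H ∈ {L, R}, coded `DAH` (e.g. `LGR` = right
hand grasps the left handle). Class conventions (fixed so confusion
matrices are comparable): class 0 = left handle (extrinsic), ipsilateral
reach (intrinsic), or touch (action); class 1 is the complement.
Within one hand the extrinsic and intrinsic labelings induce the same
partition of conditions; across hands they differ by a label flip on the
right hand's conditions. This is why, for direction transfer with
identical pools and montage, per-window accuracies under the two
labelings sum to exactly 1 — an identity the tests assert bit-exactly.

Classifiers come in groups of four that decode the same information.
Within-hand groups pair conditions differing in exactly one factor (e.g.
`RGL`/`RTL` for action). Cross-hand groups cover both transfer directions
(train left → test right and the reverse) and both values of the
non-decoded factor; for action transfer the labeling selects whether the
test pair shares the handle (extrinsic) or mirrors it (intrinsic).

## Kinematics

Wrist positions (120 Hz, 3D) are linearly gap-interpolated (gaps ≤ 0.5 s;
edge gaps are errors), smoothed with a zero-lag 4th-order 5 Hz Butterworth
filter (forward–backward, which cancels phase and doubles the effective
magnitude order), differentiated by central differences, and
polyphase-resampled to 50 Hz (120→50 is non-integer; sample-picking is
deliberately not used). Movement onset is the first time 3D speed reaches
0.01 m/s and stays at or above it for more than 0.5 s; comparisons at the
threshold use ≥, runs qualify when last-minus-first sample time strictly
exceeds the sustain, and the first qualifying run wins. Whether onset is
defined on 3D speed or a single component was an open choice; 3D speed is
used. Absence of onset is a value (no movement), consumed by rejection.

## EEG preprocessing

The 500 Hz record is common-average referenced over the 30 montage
channels (EOG excluded), band-pass filtered 0.3–4 Hz with a zero-phase
Hamming-windowed sinc FIR (high-pass stage: 0.6 Hz transition; low-pass
stage: 1 Hz transition; the two symmetric kernels are convolved, and the
combined kernel is applied with centered overlap-add convolution, so the
phase is identically zero), then decimated by 10 to 50 Hz (event times
stay in seconds). Ocular artifacts are removed by multiple regression of
each channel on [HEOG, VEOG, 1]; residuals are orthogonal to the
regressors, and the generator's known leakage coefficients make the step
verifiable against ground truth. A `none` mode skips it for artifact-free
data. Filtering runs on the continuous record before epoching (the
alternative, per-epoch filtering, was rejected to avoid edge transients).

Epochs span [−1, 2] s at 50 Hz (150 samples, 30 channels): *planning*
epochs locked to the Task cue, *execution* epochs locked to kinematic
onset. Movement-based rejection: a trial leaves the planning set iff its
onset precedes the Go cue by more than 0.5 s (onset exactly at Go − 0.5 s
is kept; the boundary rule affects ties only); the execution set
additionally drops trials with any pre-Go onset and trials without
movement. Execution rejections therefore always contain planning
rejections. No baseline correction is applied — the 0.3 Hz high-pass
handles drift.

## Decoding

Features are spatiotemporal amplitude vectors: for each 400 ms analysis
window, 9 samples per channel × 30 channels = 270 dimensions, channel-major
(feature index `c·9 + s`). At 50 Hz a 400 ms window holds 21 samples and
the nominal 9-point spacing of 0.05 s equals 2.5 samples, which does not
fall on the grid; the offsets used are `round(linspace(0, 20, 9))` =
[0, 2, 5, 8, 10, 12, 15, 18, 20] samples. Windows start at 0.0–1.4 s in
0.1 s steps (15 windows) relative to the Task cue (planning) or onset
(execution); all windows end by 1.8 s, inside the epoch. A 16th window
starting at 1.5 s would also fit the epoch, but 15 windows ending within
a margin is the layout used throughout.

PCA retains the smallest number of components explaining ≥ 85% of the
pool variance; loadings feed a two-class pooled-covariance LDA with ridge
ε = 10⁻⁶ × (trace/dim) added for invertibility (raised to an absolute
10⁻¹² floor when the pooled covariance is exactly zero, which happens on
noise-free synthetic pools). Prediction is the sign of the discriminant;
an exact tie predicts class 0. The `pca_scope` option controls whether
PCA sees the full trial pool including test trials (`pool`, the default,
which mirrors fitting "within the trial pool") or only the training split
(`train_only`, leakage-free); results name the mode, and neither is
asserted as the only valid reading.

Within-hand decoding uses 10 repetitions of stratified 10-fold
cross-validation (fold count reduced with a warning when the smallest
class has fewer than 10 trials), reshuffled per repetition from a master
seed; accuracy is the mean over the 100 held-out folds. Cross-hand
decoding trains on one hand's pair and tests on the other hand's; in
mirror mode the test trials are first re-indexed with the mirrored
montage (each position then carries its cross-midline partner, F1↔F2,
FC5↔FC6, …, an involution). Peak accuracy is the maximum over the 15
windows; peak timing is the start time of the argmax window, earliest on
ties (window start rather than center/end was an open choice and is used
consistently).

## Statistics

The chance-level threshold is exact-binomial: the smallest k with upper
tail P(X ≥ k) < α at p = 1/2, returned as k/n (an alternative inverse-CDF
convention — largest k with CDF < 1 − α, plus one — is available by flag
and recorded in reports; at n = 80 the two give 60.0% and 58.75%).
Group-level analysis averages the four classifiers of a group per subject,
counts subjects whose group mean exceeds the threshold, and compares
groups with two-tail paired t-tests (uncorrected, as is conventional for
these small designs, with Holm-adjusted p-values printed alongside).
Identical paired samples return t = 0, p = 1 and are flagged as
degenerate; constant nonzero differences are an error rather than an
infinite t. A repeated-measures ANOVA across group members is not
reimplemented; instead both per-classifier and group-mean tables are
always reported so the pooling is transparent.

## Synthetic sessions

The generator reproduces the study design: 8 blocks × 40 trials, hands
alternating by block (starting hand seeded), 10 repeats of each of the 4
task conditions per block in seeded random order; per trial Ready → Task
(+1 s) → Go (+2 s); 500 Hz EEG (30 montage channels + HEOG/VEOG), 120 Hz
wrist kinematics. Onset latencies are Normal(0.3385 s, 0.1137 s) after
Go, truncated at 0 by clipping (the mean shift at these parameters is
negligible, and clipping keeps the draw count seed-stable); optional
`early_mover_frac` / `no_move_frac` inject pathological trials for
rejection-logic testing.

Kinematics use half-sine (sinusoidal point-to-point) velocity pulses: a
0.8 s reach (peak speed at 0.4 s, contact — a speed minimum — at 0.8 s)
moving the wrist 9.5 cm toward the target handle plus forward and upward
components; grasp trials add a second vertical pulse at 0.9–1.5 s (the
lift, peaking at 1.2 s), so grasp has a double-peaked vertical velocity
profile and touch a single peak. The half-sine rises steeply enough that
threshold-crossing onset detection recovers the injected onset within two
50 Hz samples (±40 ms) on noise-free traces.

EEG is a forward-mixed sum of three sources with unit-norm scalp
patterns: an action source (grasp +, touch −) on midline-adjacent
fronto-central pairs, exactly midline-symmetric; an extrinsic direction
source (right handle +) on right parietal/centro-parietal electrodes,
identical for both hands; and an intrinsic direction source
(contralateral +) on central electrodes contralateral to the acting hand,
whose pattern for the left hand is the exact mirror permutation of the
right hand's. Each source is a raised-cosine envelope (1 s support, hence
band-limited well below 4 Hz): a planning bump centered 0.7 s after the
Task cue (amplitude 0.6) and a larger execution bump centered 0.8 s after
onset (amplitude 1.0); direction envelopes peak 0.15 s earlier than
action envelopes, so direction information precedes action information.
Noise is independent per-channel pink (1/f, flattened below 0.1 Hz) plus
white (70%/30% variance split); EOG artifacts are slow drifts plus blink
pulses leaked into the montage with known row-wise coefficients
(strongest frontally, horizontal leakage antisymmetric across the
midline). Sessions are generated in float32 and are bit-reproducible from
the seed.

Parameters that matter, with defaults:

| parameter | default | meaning |
|---|---|---|
| `w_act`, `w_ext`, `w_int` | 1 µV each | source amplitudes; zeroing one removes that encoding |
| `noise_sd` | 0.7 µV | broadband per-channel noise SD (see calibration below) |
| `eog_amp` | 15 µV | EOG drift scale (blinks 3×) |
| `onset_mean`, `onset_sd` | 0.3385 s, 0.1137 s | onset latency distribution after Go |
| `trial_period` | 6.5 s | trial slot length (covers cue sequence and movement) |

No SNR is available for the real recordings, so `noise_sd` was calibrated
once against the pipeline's own benchmark — with a single direction
source active, the matched cross-hand configuration (standard montage +
extrinsic labeling for the fixed source; mirrored montage + intrinsic for
the hand-mirrored source) must reach a group-mean peak accuracy ≥ 0.9 in
the execution phase — and fixed at 0.7 µV. At this SNR the mismatched
montage stays near chance (≈ 0.55–0.6) and planning accuracies run
≈ 0.15 lower than execution, a qualitatively realistic spread.

What the generator does **not** emulate: volume conduction from dipolar
sources (patterns are assigned directly), realistic ERP morphology,
muscle/movement artifacts, spatially correlated noise between channels,
cross-trial amplitude variability, or inter-subject pattern variability
(synthetic "subjects" differ only by noise realization and schedule).
Passing tests therefore demonstrate that the *analysis* behaves correctly
— recovers known encodings, stays at chance under label shuffling,
dissociates extrinsic from intrinsic coding through montage mirroring —
not that real EEG contains such encodings or that real-data accuracies
would match.

## Numerical choices and degenerate inputs

- FIR kernel lengths follow the Hamming rule (≈ 3.3/Δf); the record must
  exceed the kernel length or filtering errors out.
- Decimation requires an exact integer rate ratio.
- Zero-variance feature pools are an error in PCA (they occur only for
  noise-free data in signal-free windows; tests restrict windows there).
- LDA requires two classes with ≥ 2 trials each.
- Degenerate (near-constant) EOG regressors skip regression with a warning.
- Epochs that would cross record boundaries drop the trial with a warning.
- All randomness flows from explicit seeds (NumPy `SeedSequence` spawning
  for independent streams); reruns are bit-identical.

## Problem sizes used in validation

The test suite and the acceptance script run the default design (320
trials/session). The dissociation study uses 10 synthetic subjects per
encoding with fixed seeds; the null-calibration study uses 100 seeded
label shuffles of one 80-trial pool; rejection calibration pools 5
kinematics-only sessions (1600 trials). Several unit tests use 2-block
(80-trial) sessions, which preserve every structural property at lower
cost.

## Known limitations

- The EOG regression stands in for ICA-based artifact removal; it removes
  only linearly EOG-correlated activity.
- The `pool` PCA scope lets test trials influence the (unsupervised)
  feature basis; use `train_only` for strictly leakage-free estimates.
- Group statistics assume exactly four classifiers per group.
- The printed 59.3% chance threshold at "approximately 80" test samples
  does not correspond to either binomial convention at exactly n = 80
  (58.75% / 60.0%); the implementation is validated against its own exact
  tail sums instead.
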