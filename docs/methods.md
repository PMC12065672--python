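# Methods

## The task and the modeling approach

The pipeline predicts, for every clock hour of a monitoring period, whether a
participant is within the effect window of a substance-use event, from the
preceding 12 hours of engineered wearable features. Models are strictly
per-participant: a classifier is trained and evaluated only on one person's
data, which absorbs between-subject heterogeneity at the cost of very small
training sets (a few hundred windows). The two variants share one backbone —
a single 1D convolution (32 filters of width 3, ReLU) over the 12-step
window, max pooling with width 2, and flattening (per-channel length
12 → 10 → 5; flattened width 5 × 32 = 160 regardless of how many features
were selected) — and differ in how the head is trained:

* **supervised**: dropout(0.5) → sigmoid unit, minimizing the Brier score
  (mean squared error between the predicted probability and the 0/1 label);
* **self-supervised (SSL)**: the backbone is first pretrained, without ever
  consulting labels, on multi-output regression of biometric features; a
  dense(32, ReLU) → dropout(0.5) → sigmoid head is then attached and
  fine-tuned — 100 epochs with the backbone frozen, then 100 unfrozen.

Both use Adam (initial learning rate 10⁻³, batch 32), a 20% chronological
validation split with early stopping (patience 10, best weights restored)
and reduce-on-plateau (factor 0.5, patience 5, floor 10⁻⁵), and a cap of
200 epochs for the supervised model. The network, backpropagation and Adam
are implemented directly in NumPy — the model is four small matrix products
per batch — and the gradients are verified against central finite
differences for every head in the test suite.

### Design choices in training that were genuinely open

* **Pretext task.** "Multi-output regression on biometric data" admits two
  natural readings; both are implemented behind `SslConfig.pretext`. The
  default, *forecast*, regresses the feature vector of the hour immediately
  after the window (windows without a successor hour are excluded); the
  alternative, *reconstruct*, regresses the window's own per-feature means.
  Forecasting is the default because it cannot be solved by copying the
  input and therefore forces the backbone to encode temporal structure.
* **Validation tail.** The validation set is the chronologically last 20% of
  the training windows, kept in raw (non-oversampled) form, and the
  remaining 80% is what gets oversampled and fitted. Validating on
  oversampled duplicates proved actively harmful: duplicated positives
  dominate the tail, epoch-0 weights can look unbeatable, and early stopping
  then restores a near-initial network. A raw holdout gives a monotone,
  meaningful stopping signal while preserving temporal order.
* **Early stopping during SSL phases** is applied uniformly (pretraining and
  both fine-tuning phases), the conservative choice.

## Hourly features

Hours are clock-aligned and half-open, [h:00, h+1:00). Waking-hour streams
aggregate per hour: heart-rate mean, **population** standard deviation
(defined for single-record hours), max, and dominant frequency; step mean,
max and active minutes (steps > 0). The dominant frequency of a windowed
signal x(0..N−1) is the integer k in 1..⌊N/2⌋ maximizing |FFT(x)(k)|, with
ties broken toward the smallest k and 0 returned when every non-zero-bin
magnitude is below 10⁻⁹ (flat signal); it is reported in cycles per window,
not Hz, since the window is the unit of analysis. Sleep-period streams
aggregate per night (SpO2 mean, dominant frequency, minutes strictly below
90%, a night-level hypoxemia flag; breathing rate by stage; efficiency,
duration, minutes awake, onset; HRV means and LF/HF ratio of the nightly
mean powers, undefined when the HF mean is zero) and are broadcast as
constants onto all 24 hours of the calendar day *preceding* the night's end,
so a night reflects that day's use. Missing hours stay missing (NaN) at this
stage — nothing is filled before the train-only imputer sees it. HRV
"coverage" is averaged like every other HRV column.

## Labels

Each EMA row reports an approximate use time; rows with a use time after the
report time are rejected, and repeated reports of the same substance within
one clock hour collapse to a single event. An event at time t with effect
duration d hours (a per-substance table, configurable; defaults range from
1 h for nicotine to 8 h for methamphetamine and are documented placeholders
to be reviewed per deployment, not population estimates) marks hours
⌊t⌋..⌊t⌋+d−1; overlapping events union. Everything else is non-use. The
expansion starts at the floor of the reported hour to match the half-open
hourly grid.

## Preprocessing

The chronological split takes the first ⌈0.7·n⌉ hours as training. All
fitted statistics — the iterative random-forest imputer, the z-scoring
means/SDs (population SD; zero-variance features map to 0), the Gini
feature-importance forest — are fitted on the training hours/windows only
and applied unchanged to the test slice; a bit-wise test corrupts the test
slice and asserts that nothing fitted moves. Imputation runs on the hourly
matrix before windowing (equivalent content, far cheaper than imputing
overlapping windows); the per-feature regressor is a 20-tree forest inside
a round-robin imputer capped at 5 rounds — each feature is refit up to five
times, and on a few hundred hourly rows a small forest recovers conditional
means as well as a large one at a fraction of the cost. The importance
forest remains 100 trees. Feature selection keeps features with summed
(over the 12 time positions) Gini importance strictly above the
per-participant median, falling back to the top half by rank when ties
leave fewer than two. Oversampling duplicates each positive window in place
within its 24-hour segment; the number of extra copies k per positive is
the smallest integer with p(1+k) ≥ r(n+pk) for target ratio r = 0.5,
capped at 10 total copies. Feature values are never altered and test
windows never pass through it.

## Evaluation

Decisions use the ≥ rule (probability equal to the threshold predicts
positive), fixed for determinism. Metrics with zero denominators are
reported as NaN and excluded from bootstrap aggregation with a logged count
rather than imputed as 0, which would bias the means. The moving-block
bootstrap draws ⌈n/L⌉ contiguous blocks of length L = ⌊√n⌋ uniformly from
start positions 0..n−L (no wrap-around), concatenates and truncates to n,
and repeats for 30 trials; each trial is scored with the full 0.1–0.9
threshold sweep plus AUC. AUC is computed by the rank (Mann–Whitney)
formulation, ties counting half, and is reported both for the full test set
and as the bootstrap mean ± SD. Operating-threshold selection runs on a
fine 0.01-step sweep of *training* predictions: maximize specificity
subject to sensitivity ≥ 0.5 (or the converse), ties toward the threshold
nearest 0.5, with an explicit infeasibility flag when no threshold meets
the floor.

## What the synthetic cohort emulates — and what it does not

The generator reproduces the *structure* of a multi-week consumer-wearable
study: minute-level sampling, one sleep record per night, sleep-only
SpO2/HRV, EMA recall error (reported time = true time ± uniform 30 min),
realistic wear fractions via contiguous non-wear gaps of at least 30
minutes (device removal for water exposure, not isolated dropped samples),
and per-day event counts of the observed order (defaults: 28 days, wear
fraction 0.9, 2 events/day). Heart rate is a sinusoid (mean 70 bpm,
amplitude 10 bpm, period 24 h, peak 16:00) plus AR(1) noise (φ = 0.8,
innovation SD 3 bpm) — the minimal realistic autocorrelated biosignal.

The injected physiology is deliberately schematic. No published
pharmacodynamic magnitudes exist for these signals, so effect size is a
free dial, not an estimate: one unit shifts mean HR by +10 bpm during the
effect window, scales next-night RMSSD by 1 − min(0.5, 0.05·e) and lowers
next-night sleep efficiency by min(0.2, 0.02·e). Overlapping effect windows
do **not** stack — any perturbed minute carries exactly the single-event
shift — keeping synthetic HR bounded. Substance-specific response shapes,
tolerance, interactions, HR *decreases* (opioids, sedatives), and device
measurement error are all absent. Consequently, a passing signal-recovery
test shows the pipeline can find a known injected signal; it does not show
that real-world effects are detectable, and the null-calibration test shows
the pipeline does not hallucinate signal, not that real data are free of
confounds.

**Event timing and the time-of-day confound.** Use events are a homogeneous
Poisson process, by default uniform over the full day. Restricting events
to waking hours (available via `waking_hours_only`) is more realistic but
makes the zero-effect cohort predictable: with a circadian heart-rate
baseline, the hour of day is recoverable from any 12-hour window, and
diurnally concentrated labels then yield test AUCs near 0.75 with *no*
injected effect — the detector learns the clock, not physiology. This is a
genuine confound for field studies of this design, worth knowing about in
its own right; the uniform default keeps the zero-effect cohort a true
null so that calibration tests isolate physiological signal.

## Problem sizes and tolerances in the test suite

Full-pipeline properties run at the default study scale of one participant ×
28 days (672 hourly rows, ≈460 training windows): null calibration averages
supervised test AUC over 10 seeds at effect size 0 (band 0.4–0.6); signal
recovery requires AUC ≥ 0.85 on at least 7 of 10 seeds at effect size 3,
full wear, 2 events/day; the SSL comparison uses 0.35 events/day (≈ 10–15
positive training windows) and requires the SSL mean AUC within 0.05 of the
supervised mean. Oracle tests (dominant frequency vs O(N²) DFT, metrics vs
pairwise/loop brute force, trapezoidal ROC agreement to 10⁻⁹, bootstrap
contiguity) run on hundreds of random instances with n ≤ 200. Gradients are
checked against central differences at ε = 10⁻⁶ with relative tolerance
10⁻⁴.

## Known limitations

* The AR(1) innovation SD of 3 bpm gives a marginal noise SD of 5 bpm;
  real HR noise is heavier-tailed and motion-contaminated.
* Sleep-record fields (efficiency, stage breathing rates) are drawn
  independently per night; real nights are autocorrelated.
* The oversampling closed form duplicates every positive in a segment
  equally; it cannot express fractional target ratios exactly when
  positives are very few (the 10× cap binds first).
* Windows never span the train/test boundary, so a handful of boundary
  hours contribute to no test window.
* Per-participant training on ~460 windows keeps the CNN small by
  necessity; results at this scale are noisy across seeds, which is exactly
  why the evaluation reports bootstrap SDs.
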