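# Methods

`cuedmotion` implements a time-resolved inverted encoding model (IEM) for
decoding motion direction from epoched multi-sensor recordings, the group
statistics used to ask whether predictive cues modulate the decoded
representation, and a synthetic-data generator that reproduces the
experimental design so the whole pipeline can be validated end to end with
known ground truth.

## The encoding/decoding model

**Forward model.** Motion direction θ is represented by 21 hypothetical
channels with idealized tuning curves — half-wave rectified sinusoids raised
to the sixth power — whose centers tile the 180° design span [−45°, 135°)
evenly (spacing 180/21 ≈ 8.57°). Under the default `half_circle_doubled`
convention the span is one full cycle of the sinusoid,
f_i(θ) = max(0, cos(2π(θ−φ_i)/180))⁶, so the channel code wraps around the
span and covers every direction symmetrically; a `full_circle` convention
(f_i(θ) = max(0, cos(2π(θ−φ_i)/360))⁶) is provided because motion direction
is physically 360°-periodic. A trial with direction θ has hypothesized
channel amplitudes c = (f_1(θ), …, f_21(θ)); stacking trials gives
C (21 × n). The sensor data B (sensors × n) are modeled as B = W·C + N, and
W is estimated by least squares. The default estimator fits each channel
separately, w_i = B·c_iᵀ/(c_i·c_iᵀ) (`per_channel`); the multivariate normal
equations W = B·Cᵀ(CCᵀ)⁻¹ are available as `joint` and are computed with a
rank-tolerant least-squares solve, because a design containing only the 11
discrete localizer directions spans an 11-dimensional subspace of the
21-channel space. No intercept is fitted: epochs are baseline-corrected and
B and C are demeaned across trials before weight estimation.

**Inversion.** Decoding uses noise-covariance-aware spatial filters. For
each channel i, the residual E_i = B₀ − w_i·c₀ᵢ (the channel's own rank-one
prediction removed; removing the full model prediction is available via
`residual_mode="all_channels"`) yields a sensor covariance
Σ_i = E_iE_iᵀ/(n−1). Σ_i is regularized by shrinkage toward a scaled
identity, Σ_i* = (1−λ)Σ_i + λν_iI with ν_i = tr(Σ_i)/p, using the analytic
Ledoit–Wolf intensity computed from the same residual sample
(`sklearn.covariance.ledoit_wolf_shrinkage`; the analytic λ is derived for
the 1/n ML covariance and is blended here with the 1/(n−1) estimate — the
difference is O(1/n) and immaterial at the trial counts involved). The
filter is v_i = (Σ_i*)⁻¹w_i, rescaled so v_iᵀw_i = 1 (unit gain on the
channel's own pattern — the operational form of matching the filter output
magnitude to the channel activity it recovers). With Σ* = I this reduces to
normalized matched filtering. A pseudo-inverse fallback (`solver="pinv"`)
supports the unregularized λ=0 path when Σ is singular (n_trials <
n_sensors).

**Readout.** Channel estimates of test data are Ĉ = Vᵀ(B_test − b̄), with the
training-mean channel amplitudes added back so the estimates live on the
tuning-curve scale. The decoded direction is the argmax over a dense grid
(default 0.1°, recorded in results metadata) of the channel-weighted sum of
basis functions Σ_i ĉ_i f_i(θ); ties break toward the smallest angle, and an
all-flat curve returns the span midpoint with a degenerate flag.

## Time-resolved decoding

Epochs are baseline-corrected (localizer: −200–0 ms; main task: −250–0 ms on
the epoch's own time axis) and averaged in sliding windows of 28.3 ms moved
in 5 ms steps. The window width in samples is round(width·rate/1000),
reduced by one if even so windows center symmetrically: at 600 Hz the
a-priori 30 ms window gives 18 → 17 samples, matching the 28.3 ms figure.
Window centers snap to times that are integer multiples of the step where
the sample grid allows (at 600 Hz, every third sample), so decoded time axes
and cluster bounds land on round 5 ms values.

Decoder validation on the localizer uses leave-one-run-out cross-validation:
for each held-out run and time step, weights, covariances and filters are
estimated on the remaining runs at that step only, and the held-out trials
are decoded. Performance per time step is the Pearson correlation between
the presented directions and the mean decoded direction per presented
direction (Spearman optional). Because the decoder's output space is
periodic, the metric collapses presented levels modulo the basis period —
under the 180° convention −45° and 135° label the same design point — and
averages decoded directions circularly, representing each level mean in a
fixed window anchored at the smallest presented direction. The fixed window
keeps the metric unbiased on pure noise (centering the window on each level
would inject the regressor into the outcome and produce r ≈ 0.7 for a
decoder with no information); its cost is that the single edge level can
wrap to the other end of the window at very low SNR, denting r at isolated
time steps. The literal arithmetic-mean variant is available with
`period=None`.

Each participant's training peak is the argmax of their performance curve
within the group-level window (90–110 ms in the reference configuration,
matching the earliest significant group cluster); the final model is trained
on the peak step plus two neighbors on either side, pooled as extra
observations with a single demeaning over the pooled sample (whether to
demean per step is genuinely open; pooled is the default and the test data
are demeaned with the same pooled means). That model is then applied at
every window step of the main task, yielding a time × trials decoded-direction
matrix restricted to −250–500 ms for statistics.

## Statistics

* **Participant QC** — Pearson r between the presented directions and the
  mean reported direction per presented direction; pass at r ≥ 0.9.
* **Perceptual bias** — mean reported direction when 63° was cued minus when
  27° was cued, with the presented × predicted cells weighted equally. Cell
  balancing is essential: with 60% cue validity the raw conditional means
  differ by 18° by design alone, while the balanced difference isolates the
  cue-induced shift (expected 36·w under the report model below).
* **Cue effect on decoding** — per time step, decoded directions are
  averaged per (presented, predicted) cell, cells are averaged with equal
  weight within each predicted level, and the cue27 level is subtracted from
  the cue63 level; empty cells are dropped from both levels symmetrically.
* **Cluster-based permutation tests** — pointwise t statistics thresholded at
  the one-tailed p = 0.05 critical value; contiguous supra-threshold runs
  form clusters with mass = Σt; the null distribution is the maximum cluster
  mass over 10,000 permutations (participant-wise sign flips for one-sample
  tests — the standard exchangeability argument for within-subject effects —
  and group-label reassignment for between-groups tests). Exhaustive sign
  enumeration replaces sampling when 2^n ≤ n_perm. p-values include the
  observed statistic in the null ((1+k)/(1+n)), so p = 0 is impossible.
  Cluster effect size d is the mean/SD across participants of the
  within-cluster participant means. Correlation timecourses are Fisher
  r-to-Z transformed (z = atanh r) before group tests.
* **Trialwise brain–behavior partial correlation** — the presented direction
  is regressed out of both the decoded and the reported direction (linear
  covariate by default; categorical per-level demeaning optional — the right
  choice is not determinable and both are provided), and the residuals are
  correlated per time step.
* **Post hoc split** — participants with positive perceptual bias vs the
  rest (a bias of exactly 0 counts as unbiased); the cue effect is compared
  between groups with the two-sample cluster test (two-tailed by default,
  so relabeling the groups flips cluster signs but preserves p).

## Synthetic data generator

Each simulated participant has a ground truth: random Gaussian channel
patterns W_true (sensors × 21, scaled by 1/√p), a spatially correlated noise
covariance (corr ρ^|i−j| between sensors i and j, ρ = 0.6, per-sensor SD
1.0 — correlated in space, white in time, because the decoder models spatial
covariance only), and an evoked gain g(t) = (t/100)·e^(1−t/100) for t ≥ 0
(zero before stimulus onset, unit peak at 100 ms). Epochs are
data(trial, :, t) = W_true·f(θ_presented)·g(t) + noise. The designs mirror
the experiment: localizer blocks of 88 trials (8 each of the 11 directions
−45…135°, 100% coherence, pseudo-random order) and cued main-task runs of
60 trials (cues balanced; presented = cued direction with 60% probability,
each of the four other directions 10%, exact counts where divisible).

The cue manipulation enters twice. Neurally, an optional *expectation
template* adds amplitude·W_true·f(θ_cued) between 135 and 180 ms on cued
trials — a literal reactivation of the cued direction's sensor pattern.
Behaviorally, reports mix stimulus and cue linearly:
reported = (1−w)·presented + w·cued + N(0, σ²), σ = 8°. The directions used
(9–81°) sit far from the span edges, so no circular wrapping is needed. The
weight w is +1/18 for the 17 "attracted" participants (expected bias +2°)
and −1/30 for the 7 others (expected bias −1.2°); the slight repulsion in
the minority makes the post hoc split reproduce a 17/7 structure, which a
w = 0 minority cannot (its bias sign would be a coin flip). No published
generative model exists for these reports; the weighted-average form is this
package's choice as the simplest mechanism producing an attractive bias.

The template amplitude default (0.19) was calibrated once so that the
single-time-point cue-effect d at 150 ms is ≈ 0.7 at the detection-study
scale, a deliberate design point for validating detection power.

What the generator does **not** emulate: continuous (non-epoched) recording,
artifacts, eye movements, head motion, cue acoustics, reaction times,
temporally correlated noise, or any systematic difference between localizer
and main-task response topographies. Passing tests therefore demonstrate
that the pipeline is correct and well-calibrated under its own assumptions,
not that the scientific effect exists in real recordings.

## Problem sizes and numerical choices

All operations are dimension-generic (the same code decodes 2-channel gaze
data). The analyses in this repository run reduced sensor arrays so the full
study executes in minutes on one core: 16 sensors, 2 localizer blocks and 3
cued runs per participant for the cohort analyses (the detection study uses
a 0.5° readout grid); the shrinkage benchmark uses 128 sensors with 88
training trials to exercise the singular-covariance regime; validation of
exact recovery uses 16 sensors and noise-free epochs. Permutation counts are
10,000 for reported analyses and 1,000 inside the repeated validation loops.
Stage seeds derive deterministically from a master seed and stage name
(CRC32, below 2³¹), making every run a pure function of (config, seed).

Known limitations: the argmax readout is winner-take-all, so small cue
effects appear as occasional trial-level jumps toward the cued direction
rather than graded shifts, and effect magnitudes are therefore not
comparable across SNR regimes; the `full_circle` basis convention has a
one-sided-coverage readout bias (up to ~20°) for directions at the span
edges, because channels exist only inside the span — the default wrapped
convention avoids this at the price of aliasing −45°/135°; and the
between-groups test needs at least two participants per group, so extreme
splits refuse rather than degrade.
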