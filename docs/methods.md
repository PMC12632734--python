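# Methods

`wmstates` implements a population-level analysis suite for trial-structured
extracellular recordings from monkeys performing the oculomotor delayed
response (ODR) task, together with a synthetic spike-train generator that
reproduces the statistical structure the analyses assume. This note
documents the models, the parameters that matter, the numerical choices,
and what the synthetic studies do and do not establish.

## Task frame and data model

Time is measured in seconds from cue onset. Epochs are half-open:
fixation [−1, 0), cue [0, 0.5), delay [0.5, 3.5), response [3.5, 4.1).
Cues occupy eight canonical angles 45° apart; task variants with finer cue
spacing (e.g. 120 locations 3° apart) are grouped to the nearest canonical
angle before any analysis. A session is three tables — spike events
(unit, trial, time), trials (cue location, outcome, reaction time), units
(area, depth, single/multi) — validated for referential integrity and time
bounds on load. Aborted trials are simply absent; the package never models
them.

## Per-unit statistics

* **Binning.** Sliding bins of width *w* and step *s* over a span produce
  `floor((span − w)/s) + 1` bins; counts are divided by *w*. Illustrative
  rate traces use 50 ms abutting bins; decoding and information time
  courses use 100 ms windows stepped by 50 ms.
* **Spatial selectivity.** One-way ANOVA of per-trial epoch-mean firing
  rates over the eight cue groups, plus a gate requiring at least
  2 spikes/s at the best location — near-silent units otherwise produce
  spurious small p-values. Rates (spikes/duration), not counts, enter the
  ANOVA.
* **Preferred location.** The spike-count-weighted circular mean
  `T = Σ_j n_j e^{iθ_j} / Σ_j n_j` of the eight cue angles, with mean delay
  spike counts as weights; the resultant angle is the preferred location
  and its modulus (0–1) the concentration. A vanishing resultant
  (perfectly symmetric counts) is flagged undefined and such units are
  excluded, with a logged count, from preferred-location-conditioned
  analyses.
* **Laminar bands.** Depth from the shallowest spiking contact, half-open
  bands: superficial [0, 0.8) mm, middle [0.8, 1.2) mm, deep from 1.2 mm.
  The 1.2 mm boundary is assigned to deep.
* **Delay elevation.** Per 50 ms delay bin, a paired one-sided t-test of
  the population rate (mean over units) against the same trials' mean
  fixation rate, Benjamini–Hochberg corrected at q = 0.05 across the 60
  delay bins.

## ω² information time courses

Bias-corrected percentage of explained variance per unit and bin:
`ω² = (SS_between − df·MSE) / (SS_total + MSE) × 100`, df = 7 for eight cue
groups. Negative values are retained — clipping would bias the one-sample
test of "information > 0" whose null is centered at zero. Degenerate
constant data return 0. Trials are stratified (downsampled without
replacement to the smallest cue group) once per call with a seeded RNG, so
the same balanced subset enters every bin; stratifying per bin would mix
different trial subsets across the time course.

## Decoding

Lasso-regularized logistic regression (λ = 0.01) on firing-rate features
z-scored per (unit, bin) across trials, leave-one-trial-out: a fresh model
per training bin on n−1 trials, evaluated on the held-out trial at the same
bin (or at all bins for cross-temporal matrices). Eight-way decoding is
one-vs-all over the eight locations with argmax-of-margin prediction;
binary "diametric" decoding separates a location from its 180° opposite,
and the two-class softmax of the symmetric per-class scores (±m/2, where m
is the decision margin) gives the posterior "confidence" of the true class.
Zero-variance features are zeroed, not dropped, so feature indices are
stable across folds.

**Solver.** The LOO-times-label-shuffle workload solves ~10⁵ small lasso-
logistic problems per session, so the default engine is a compiled
(numba) second-order coordinate descent — the same newGLMNET-style update
liblinear uses, with an objective that matches liblinear exactly, including
its penalized intercept column — solved in batch with every leave-one-out
fold warm-started from the all-trial solution of the same problem. Solver
tolerance is 10⁻⁶ on the accepted Newton-step coordinate change and the
configuration is deterministic, so repeated runs agree to reported
precision. scikit-learn's liblinear remains available as a reference
engine; the two agree on held-out margins to ~10⁻⁴, far below any decision
boundary at these trial counts.

**Z-scoring caveat.** Full-matrix z-scoring (the default) constrains every
feature to sum to zero across trials, so under leave-one-out the held-out
trial equals minus the sum of the training trials — a label leak that
biases confidence optimistically at small trial counts (measurable below
~40 trials per binary problem, negligible above). A fold-safe z-scoring
option (statistics from the training fold only) removes the bias at extra
cost; the chance-calibration studies use trial counts at which the default
is unbiased within Monte-Carlo error.

## On/off state labeling

For each trial, the delay-period confidence trace is z-scored against a
label-shuffle null: the decode is repeated 50 times with training labels
permuted, giving a per-(trial, bin) null mean and s.d. Candidate on-states
are maximal runs of z > 1.64; a run is accepted when its cluster mass (sum
of z within the run) exceeds the 95th percentile of the null
max-cluster-mass distribution, obtained by applying the identical
clustering to each shuffled trace — the max-statistic version of
cluster correction, which controls family-wise error over time. Off-states
are maximal runs of z < 0.3 lasting at least 3 consecutive bins of the
decoder grid (50 ms steps, 100 ms windows). If a bin's null s.d. is zero
(possible with 50 shuffles), the pooled s.d. over bins substitutes, with a
warning. The null is per-trial, and the labeled confidence is that of the
trial's *true* cue class (on error trials as well).

## State tuning curves and cross-areal transfer

Per unit, the z-scored delay rate is averaged over on-labeled (trial, bin)
cells for each of the eight locations, likewise for off-labeled cells; both
curves are circularly rotated so the argmax of their sum sits at index 0.
Aligning to a data-dependent argmax manufactures a peak, so the curves are
debiased by subtracting the mean of 1000 curves recomputed with the
*state labels* permuted across trials (each trial's rates paired with
another trial's on/off masks), each shuffle re-picking and re-aligning its
own preferred location. The subtracted mean is the state-independent
tuning curve plus the alignment bias, so the debiased functions have
expectation zero whenever the labels carry no information about the rates
— the calibration property the cross-areal null test relies on — and
genuine on/off structure survives as the signed excess over the
state-independent curve (on positive, off negative at the preferred
location). An alternative reading — permuting *cue-location* labels, which
subtracts only the alignment bias and leaves the raw tuning in both curves
— was rejected: it fails the zero-expectation property, and its
interaction between argmax alignment and the unequal on/off noise levels
produces a systematic spurious "depth reduction" at desk scale. Tuning
depth is curve[0] − curve[4] (preferred minus diametric); the off-vs-on
reduction is reported in percent and exceeds 100% when the off excess goes
negative, as complete flattening implies. Cross-areal transfer computes the target area's
curves and rates within the source area's labels, with paired t-tests on
per-unit on-vs-off and on-vs-overall rates and a one-sample t-test across
units on the depth difference. The minimum source-population size is a
parameter (80 units for full-scale recordings); the desk-scale synthetic
studies use their session's own 15 units per area, since the label-shuffle
null s.d. scales with the unit/trial ratio and 80-unit sessions would need
several hundred trials per location pair.

## Population-ISI silence statistic

For each population of at least five delay-selective units sharing a
preferred location, spikes of all members are pooled within each delay
period and successive inter-spike intervals computed — never across trial
boundaries, where intervals would be concatenation artifacts. The maximum
pooled ISI and the pooled rate (total spikes / total delay time) give one
point per population. The null permutes each neuron's trial indices
independently and reassembles pseudo-trials (10,000 iterations by
default), conserving spike counts — and hence the rate — exactly, while
destroying within-trial coordination. Across populations, OLS of
log₁₀(maxISI) on log₁₀(rate) is run once empirically and once per shuffle
iteration (iteration-matched), and the primary one-sided permutation p is
the fraction of null slopes at least as flat (≥, slopes being negative) as
the empirical slope, with the add-one estimator; the opposite tail and an
intercept comparison are also reported. Coordinated silences leave maxISI
pinned near the silence duration regardless of rate in high-rate
populations, flattening the slope; trial shuffling restores the Poisson
1/rate scaling.

The validation harness reproduces the surrogate design: 50 populations,
neuron counts uniform on {2..20}, trial counts uniform on {10..20}, 3 s
trials, per-neuron rates discrete-uniform 1–20 Hz, and 1–3 silent windows
of 100 ms per trial placed uniformly (overlap allowed; deletion acts on
the union), shared by all neurons of the trial. A per-neuron-independent
silence mode is provided for contrast. The acceptance runs use 1,000
shuffle iterations; calibration of the permutation p uses disjoint
iteration blocks so each repetition has an exchangeable draw and an
independent null.

## Beta mixture, spectra, reaction times

Delay confidence is modeled as a single beta versus a two-component beta
mixture fitted by EM (responsibilities, then weighted beta MLE per
component via L-BFGS on log-shape parameters), with a
method-of-moments quantile-split start plus 9 random restarts, best
likelihood kept; values are clamped to [10⁻⁶, 1−10⁻⁶] since saturated
classifiers emit exact 0/1. ΔAIC and ΔBIC compare k = 5 against k = 2
parameters from the same log-likelihood code path, so
ΔBIC − ΔAIC = 3(ln n − 2) holds identically. The mixture log-likelihood is
floored at the single-beta value (the models are nested; EM can only fall
short by numerical convergence).

State rhythmicity uses Welch's method on mean-centered per-trial binary
state series: 2 s Hamming windows, 50% overlap, 1024-point FFT
(zero-padded), one-sided, averaged across trials; trials shorter than one
window are skipped and counted.

The reaction-time analysis fits, per session, RT ~ State (state of the bin
containing the go cue; trials with neither label are excluded), giving
β_state = RT_on − RT_off in ms; inference on the across-session mean uses a
nonparametric bootstrap over sessions (B = 10,000), with the one-sided p
the proportion of bootstrap means ≥ 0 (both tails reported, floored at
1/B). Because a single null cohort's p is uniform on (0, 1) by
construction, the null-calibration study reports the median p over
replicate null cohorts, which concentrates at 0.5. State counts near the end of the delay use any-overlap membership in
the last 0.5 s and a three-way ANOVA (outcome × preference × state, all
interactions) on per-session cell means.

## Synthetic study conditions

The generator emulates the recorded sessions' statistical structure, not
their biophysics: homogeneous Poisson baselines (discrete-uniform 1–20 Hz
per neuron), multiplicative von Mises tuning
`1 + (gain−1)·exp(κ(cos Δ − 1))` active from cue onset through the response
epoch, and optional coordinated gating in which the tuned modulation is
scaled by an off-multiplier (0 = complete flattening, baseline persists)
during off intervals of an alternating train with exponential dwell times,
shared across all neurons of an area (or across areas). Off states are
transient: the default alternation rate 0.25 Hz with duty 0.3 gives mean
on-dwell 3 s and off-dwell 1.2 s, in the several-hundred-ms-to-second
range of observed mnemonic fluctuations. Behavior is linked to the gating
truth: RT = base (250 ms) + β·1[on at go] + Gaussian noise (30 ms), and
error probability 0.05 + 0.4 × (off fraction in the last 0.5 s of delay).

Canonical desk-scale conditions, chosen once for adequate statistical
power at these session sizes and then fixed:

* **State detection**: two areas × 15 units, 50 trials/location, gain 8,
  κ 2 — the unit/trial ratio at which the 50-shuffle null is tight enough
  (s.d. ≈ 0.16) for z > 1.64 clusters. The independent-gating control (a
  calibration check of the transfer test) runs at 35 trials/location.
* **Pseudo-population contrast**: one area of 200 units, 18
  trials/location, gain 2.5, duty 0.4 — many weak units, so population
  accuracy is far above threshold while per-unit splicing noise stays
  small; decoded at 4 delay bins (100 ms windows, 750 ms steps), 100
  pseudo-populations. The ungated null control runs at 100 units and 12
  trials/location.
* **Chance calibration**: 30 untuned units, 20 trials/location.
* **Preferred-location recovery**: 60 units, 25 trials/location, κ 2,
  gain 3.

What passing these studies shows: the estimators recover structure they
were built for, at their stated error rates, under Poisson spiking with
the assumed gating model. What they do not show: robustness to
non-Poisson irregularity, rate drift, correlated noise beyond shared
gating, electrode artifacts, or eye-movement confounds present in real
recordings.

## Known limitations

* **Off-interval coverage.** With flatten-only gating, confidence during
  true off states is chance-level rather than below-chance, so z < 0.3
  covers only ~55% of true off bins whatever the session size, and the
  3-consecutive-bin rule fragments the remainder; detected off intervals
  therefore overlap ground-truth off time with Jaccard ≈ 0.35–0.40 (on
  states: ≈ 0.9). The off-labeling rule is a conservative detector of
  within-off segments, not a segmenter of the full off time course; the
  off-state *tuning* consequences (depth collapse, cross-areal transfer)
  are recovered essentially in full.
* The LOO z-scoring leak above makes small-session confidences
  optimistically biased under the literal full-matrix convention; use the
  fold-safe option for sessions with few trials.
* EM for the beta mixture can be slow to converge along the ridge between
  overlapping components; the likelihood tolerance (10⁻⁷ relative) and
  restart count trade accuracy for runtime.
* Pseudo-population decoding differences are regime-dependent: with few
  strong units, splicing *lowers* accuracy (Bernoulli gating noise); the
  recorded-data direction (pseudo ≥ simultaneous) emerges in the
  many-weak-units, near-ceiling regime the canonical conditions use.
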