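# Methods

This note documents the model, the numerical and design choices behind
`swimddm`, and what the synthetic validation suite does and does not
establish.

## The decision process

The decision variable follows a leaky/self-reinforcing drift-diffusion
(Ornstein–Uhlenbeck) process between absorbing bounds at ±B:

    dx = (μ·f(I) − λ·x) dt + σ dW,    f(I) = √I.

The square-root transform of the motion coherence `I` is a fixed
Weber-law-style compression; leaving its exponent free makes repeated
fits disagree, so it is not a parameter. The bound is fixed at B = 1:
scaling (B, σ, μ) jointly leaves the event statistics unchanged (the
test suite verifies that matched noise streams give identical event
times under such scaling), so B is redundant with the other amplitudes.

A bound hit at |x| ≥ B emits a decision event — `correct` for +B,
`incorrect` for −B; only one stimulus direction is simulated because
the model is left/right symmetric. After an event, `x ← r·sign(x)·B`
and the integrator freezes for the delay δ.

### Integration scheme

Explicit forward Euler with dt = 0.01 s. The Wiener increment is
`σ·√dt·N(0,1)`: this is the scaling that makes event statistics
invariant to the choice of dt (verified by a dt-consistency test at
dt = 0.005 vs 0.01). Bound hits are tested at the end of each step
with no within-step interpolation, so event times carry an error of at
most one dt — consistent with all analytic-ISI tolerances being ±dt.
The delay is ⌈δ/dt⌉ frozen steps starting the step after the event;
the ISI clock keeps running during the delay (events are point events).
Noise draws are consumed during frozen steps too, which keeps matched
seeds aligned under bound rescaling.

The state starts at x₀ = 0 per coherence session and is *not* reset at
trial boundaries within a session (persistent-state phenomenology);
events emitted during rest phases are recorded with `phase="rest"` and
excluded from fitting histograms. A divergence guard aborts if
|x| > 10·B between events; with the default search space and dt this is
unreachable except for pathological λ·dt, and it protects the optimizer
from non-finite losses.

## Histograms and loss

ISIs of correct and incorrect events are binned per coherence into 40
half-open bins over [0, 2) s (bin width 0.05 s = 5 dt, for robust
binning of simulated event times). Only steady-state events — at least
2 s after stimulus onset — are used, and the first event of a session
(whose "ISI" is measured from the session start) is excluded. Heights
are normalized by the total stimulation time of that coherence.

Two height conventions are supported: `density` (default;
count/(T·Δτ)) and `per_bin` (count/T). They differ by the constant Δτ
only, so the loss is rescaled uniformly and fits are unaffected. The
histogram *area* A(c, label) = Σh·Δτ is the in-range event rate
(events/s) and is identical under both conventions.

The loss between a target and a model histogram pair is the weighted
Kullback–Leibler divergence DKL*(P0,P1,P2) = Σ P0·P1·ln(P1/P2),
computed in both orientations — d0 = DKL*(Pt,Pt,Pm),
d1 = DKL*(Pt,Pm,Pt) — with the larger taken, then averaged over the
eight (coherence, label) pairs. Weighting by the target height makes
errors at the ISI-distribution peak dominate errors in the flat tail
(a property test asserts this dominance on randomized histograms).
Conventions for degenerate bins: 0·ln(·) := 0, and zero denominator
bins are clamped at ε = 10⁻⁶·max(1, max(P1)) before the log, which
preserves exact zero loss at equality while bounding any single bin's
contribution. Pairs empty on both sides contribute zero.

## Target-model library

Uniform draws over the search space mostly produce silent or
machine-gun models, so validation targets are rejection-sampled:
a candidate is simulated for 900 s per coherence (continuous segments)
and kept only if its histograms satisfy the acceptability criteria —
per-coherence activity floors A_correct(c) ≥ 0.005·c and
A_incorrect(c) ≥ 0.005·(1−c), activity at full coherence
(A_correct(1) > 0.01 or A_incorrect(1) > 0.01), coherence growth with
label dominance (A_correct(1) > 1.33·A_correct(0) and
A_correct(1) > 3.33·A_incorrect(1), or the mirrored incorrect-dominant
clause), and a per-bin height ceiling h ≤ 0.15 that rejects unnaturally
regular swimming. The ceiling is evaluated on heights in per-bin
count/T units regardless of the storage convention: in density units
0.15 would cap event rates near 0.075 swims/s, far below the observed
roughly-once-per-second regime the criteria are meant to select, so a
convention-dependent reading would be meaningless.

Default search space (σ ∈ [0.05, 3], μ ∈ [0, 8], λ ∈ [−8, 8],
r ∈ [0, 1], δ ∈ [0, 1] s): with B = 1 these ranges admit the observed
0.1–3 swims/s regime without pinning the reset or delay at their
limits. About 3% of uniform draws pass the criteria at these settings.

## Fitting

Bayesian optimization over the 5-D box: a Gaussian-process surrogate
(constant × Matern-5/2 anisotropic kernel + white noise, inputs
normalized to the unit cube) is fit to all evaluations after `n_init`
uniform-random probes. The GP models the *log* of the loss — the loss
is positive with a dynamic range of orders of magnitude across the
space, and the log-transform keeps the surrogate from being dominated
by the worst region. Each proposal maximizes an acquisition drawn at
random from {LCB (k = 1.96), EI, PI} (a hedged portfolio) over a cloud
of uniform candidates plus candidates jittered around the incumbent at
three scales. The EI/PI incumbent is the minimum *GP-predicted mean*
at observed points, not the raw minimum — the raw minimum of a noisy
loss is biased low and starves the acquisitions. GP hyperparameters
are re-optimized every 5 iterations (refits in between hold them
fixed). Acquisition optimization by candidate-set maximization keeps
each iteration cheap relative to the simulation call.

Each evaluation re-simulates the model with a seed derived
deterministically from the master seed and the call index, so a fit is
reproducible bit-for-bit. `trials_per_eval` controls the evaluation
data volume: with a continuous-protocol target, an evaluation
simulates `trials_per_eval × 30 s` of stimulation per coherence, using
the same protocol as the target, so target and model histograms are
directly comparable. Reported scales: the full-scale setting is 1,500
calls × 2,000 trials per evaluation; the package's reduced desk-scale
setting is 300 calls × 300 trials.  At that scale the 10-model
recovery medians for σ, μ, λ, δ land below 0.11 in range-normalized
units; the reset factor r is the least identifiable parameter and its
median varies between ≈ 0.1 and ≈ 0.25 across library draws (see
Known limitations).

Recovery is quantified per parameter by e(j) = |p(j) − p*| / (m_max −
m_min); for real data, where p* is unknown, the analogous distance to
the final estimate d(j) is reported. `repeat_fit` runs independent
seeds and reports medians with 10th–90th percentile intervals.

A pure-random-search mode at the same interface serves as a
correctness baseline: with a ~10× budget it reaches comparable losses,
i.e. the GP buys efficiency, not correctness (tested).

## Validation suite

**Sensitivity.** For each library model, each parameter is perturbed
by ±5/10/25/50% of its search-range width (values leaving the space
are skipped, not clamped); the loss of the perturbed simulation
against the model's reference simulation is compared with the
unperturbed re-simulation noise floor by a two-sided Mann–Whitney U
test. The two signed levels of one magnitude are pooled into a single
sample before testing, matching how onsets are quoted (±x%). The
smallest significant magnitude is the parameter's onset. Under the
default conditions (20 models, 900 s per coherence) the diffusion
onset is robustly 5%; the reset onset is grid-unstable across master
seeds (10–50%) because the 10% and 25% levels straddle the
significance boundary at this statistical power.

**Duration sweep.** Fresh targets of each tested duration are fitted
and the pooled per-parameter normalized errors are compared with
uniform-random parameter draws (expected per-parameter error 1/3 under
a uniform draw) by Mann–Whitney U; the baseline side uses 20 random
draws per model, since drawing is free and a small baseline sample
makes the test hinge on luck. The package's reduced sweep (5 models,
durations 120/1,200/3,600 s, 200-call fits) checks that fits beat
random draws from 1,200 s per coherence upward.

**Histogram-noise robustness.** `add_histogram_noise` perturbs each
bin with i.i.d. N(0, σ²) noise; heights are rates, so negative results
are clipped at 0 and the clipped fraction is recorded on the result.

**Bootstrap statistics.** The median test imposes the null by
translation: each group is centered on its own median and resampled
with replacement from itself; the p-value is the fraction of resample
pairs whose |Δmedian| reaches the observed one. (Resampling the pooled
data instead is badly conservative for medians at small n — measured
type-I ≈ 0 versus ≈ 0.04 for the translation variant at n = 20,
α = 0.05.) Identical groups give p = 1 by construction. The median CI
is the 5th–95th percentile of the bootstrapped median. The CV uses the
sample (n−1) standard deviation — group sizes are small. Group trends
over ordinal covariates (e.g. age) use ordinary least squares with the
standard t-test on the slope, and pairwise group comparisons are
Bonferroni-corrected (α/number-of-pairs; 10 pairs for five groups give
the 0.005 threshold).

## Synthetic data generators

`gen_target_dataset` simulates a parameter set and histograms it in
one call — the canonical entry point for recovery experiments (900 s
per coherence = 3,600 s total at the default four coherences, matching
the session length of the behavioral assay).

`gen_orientation_trace` emulates the tracker output: a 90 Hz heading
trace that is piecewise constant with raised-cosine ramps at
prescribed bout times/angles plus sub-threshold Gaussian jitter
(default 0.1°). It reproduces the *detectability* structure of real
traces — discrete bouts on a quiet baseline — but not their slow
drifts, tracking dropouts, head/tail swaps, or wall interactions; the
QC criteria that target those artefacts are therefore exercised with
constructed event tables, not with this generator. Round-trip tests on
these traces (100% bout-count recovery, < 1° angle error) certify the
detection pipeline's logic, not its robustness to real-world noise.

## Swim-event extraction

The heading-orientation trace is analyzed with a centered rolling
*population* variance over 50 ms of frames (ties in the frame count
round up, giving an odd 5-frame window at 90 Hz; edges use truncated
windows). The estimator choice (population vs sample) only rescales
the empirical thresholds slightly and is documented so they can be
recalibrated. Bouts start where the variance stays above 1 deg² for at
least 20 ms and end where it stays below 0.5 deg² for at least 50 ms.
The orientation change is read 2 frames outside the detected interval
(the centered window otherwise clips slow ramp onsets of small turns);
|Δ| ≤ 3° is a forward swim, excluded from the binary statistics but
tallied. Turns toward the coherent-motion direction are `correct`;
during 0%-coherence trials, labels are taken relative to the trial's
counterbalanced nominal direction, making the expected correct
fraction 50% by construction. Orientation input is assumed unwrapped;
a helper removes modulo-360 jumps.

Quality control applies, in order: event flags (ISI ≥ 30 s, mean swim
speed ≥ 6 cm/s, contour area ≥ 2000 px, |turn| > 150°; criteria whose
input columns are absent are skipped and recorded), trial drops
(> 5% flagged swims), and the animal-level drop (mean rate
< 0.375 swims/s). QC runs before the ±3° forward-swim exclusion.

## Known limitations

* σ(t), μ(t), λ(t) are constants within a model; the time-varying
  generalization is out of scope.
* Recovery at the desk scale leaves a near-flat loss region around the
  optimum: reset and delay are the least identifiable parameters, and
  occasional fits land in a distinct (high-λ, high-drive) basin whose
  finite-data loss is comparable — more evaluation trials and budget
  shrink both effects.
* For high-leak models the reset is forgotten within ≈ 1/λ seconds, so
  r and δ trade off along a flat valley; with 900 s-per-coherence
  targets, the finite-sample loss minimum can sit far from the true
  (r, δ) split even when probed directly (the loss at a wrong split is
  sometimes *lower* than at the true one). This is a data-volume
  limit, not an optimizer artefact, and it makes desk-scale median
  r-recovery depend on the library draw.
* The acceptability criteria exclude very regular, sharply peaked ISI
  distributions; parameter sets outside the accepted regime (e.g.
  strong drive with weak leak and long delay) can be genuinely
  non-identifiable from 900 s targets.
* The bootstrap median test is slightly conservative (type-I ≈ 0.04 at
  α = 0.05, n = 20).
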