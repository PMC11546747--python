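# Methods

This note documents the models, the synthetic-data generators, numerical
choices, and the design decisions taken where the procedure was genuinely
open.  Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Task schedules and agent simulation

The progressive-ratio (PR) requirement for trial *i* is
`round(5·e^(0.2·i)) − 5` with half-away-from-zero rounding (no half-cases
occur for i ≤ 20).  This generating rule reproduces the canonical printed
16-entry progression (1, 2, 4, … 118) exactly and extends it smoothly; the
extension beyond trial 16 is an assumption, since only 16 ratios are
printed.  The PR termination clock is a sliding 10-minute window from the
last reward (or session start), reset on each reward.

Demand-task price progressions are fixed constants: food 180, 90, 45, 15,
5 presses/pellet per 10-min bin (descending to avoid early satiation);
remifentanil 6, 10, 16, 25, 40, 63, 100, 158 presses/infusion.

The session-simulation agent is scaffolding, not a behavioral model: a
homogeneous Poisson presser (rate in presses/s, suspended during the 2-s
post-reward timeout) with an optional quit rule once the current ratio
exceeds a persistence limit.  Completing a ratio triggers the cue; reward
follows 2 s after cue onset, matching the cue (0–2 s) and reward (2–7 s)
analysis windows used downstream.

Go/no-go plans hold 64 trials (32 go, 32 no-go) in blocks of 10–11 with
near-even per-block quotas whose odd-block imbalances alternate; order is
shuffled within blocks.  The exact pseudorandomization scheme of the
original task is not documented, so any 32/32, block-respecting scheme is
admissible; ours is seeded and deterministic.  No-go cues extend from 5 s
(phase 1) to 10 s (phase 2).

## Synthetic photometry

Two channels share a single-exponential bleaching trend and a band-limited
motion artifact (low-pass filtered white noise, default 1 Hz, 2% of
baseline), the isosbestic channel with a channel-specific artifact gain
(default 0.8).  Transients — difference-of-exponentials kernels with
0.1 s rise and 0.5 s decay, typical of the dopamine sensor's kinetics —
appear only on the signal channel, at the planted times or at cue/reward
events.  Default sampling rate 100 Hz (the acquisition hardware rate is
not documented; configurable).  With the default gain mismatch the
corrected trace retains ~20% of the artifact, which is realistic but means
exact transient-count recovery is only asserted on quiet-baseline settings
(matched gain, low noise).  What passing tests show about real data is
therefore limited to: the regression removes whatever artifact component
is common to both channels, and prominence-thresholded detection counts
well-isolated transients exactly.

## Photometry processing

Detrending fits the (optionally 6 Hz zero-phase Butterworth-filtered,
order 6) isosbestic channel onto the signal channel by OLS over the full
session and returns ΔF/F = (signal − fit)/fit; a subtraction-only mode
returns the raw residual.  The ratio mode is not idempotent — its output
is near zero-mean, so re-fitting would divide by a near-zero baseline —
whereas the subtraction mode is (re-application changes the trace by
< 1e-8); the idempotence property is asserted for that mode.  The filter
is applied forward-backward to avoid peri-event latency shifts (the
original filter ran causally at acquisition).

PSTH z-scoring is per trial against that trial's own −4..−2 s baseline, so
the baseline-window mean is 0 and SD 1 exactly by construction.  Trials
without full span coverage are dropped with a warning.  Window AUCs use
the trapezoidal rule with endpoint interpolation, so a constant trace of
1 over a 2-s window integrates to exactly 2 z·s regardless of bin phase.
Transient prominence uses the standard topographic definition; the
threshold of 1 applies in the trace's own units (% ΔF/F0 for spontaneous
catalogs, z for PSTH-domain analyses) — which unit the original analysis
used is not documented, so both are supported.

## Synthetic spike sessions

Units are inhomogeneous-Poisson with uniform baseline rates (2–10 Hz) and
a planted profile: cue-activated/inhibited (0–2 s), reward-
activated/inhibited (2–7 s), press-inhibited (−2..2 s, the pressing epoch
around ratio completion), or nonencoding.  Activated profiles multiply the
in-window rate by an effective gain 1 + (gain−1)·drift(trial) (default
gain 3, flat drift); inhibited profiles divide by it.  Generation is exact
(extra Poisson spikes for excitation, thinning for inhibition).  The
generator does not emulate bursting, refractoriness, rate nonstationarity
or correlated noise across units; cluster-recovery results transfer to
real data only insofar as encoding classes differ in window-mean firing
on the scale of the planted gains.

## Single-unit encoding analysis

Firing is binned at 100 ms (the kernel is specified in bins, the bin width
is not; configurable), normalized to the unit's session-mean rate,
z-scored across units per time bin (within session; a pooling flag would
be needed for cross-session populations), and smoothed with a truncated
renormalized Gaussian kernel of 8 bins, σ = 3 bins.

Features per unit: (i) number of transients, (ii) time of the first
transient after cue onset (sentinel: end of the search window), (iii) mean
cue-window activity and (iv) mean reward-window activity in z units.
Transients are contiguous excursions of the smoothed *session-mean-
normalized rate* at least 50% away from the unit's average firing,
with excursions separated by < 0.3 s merged (threshold wobble).  An
excursion rule on the cross-unit z trace (|z| ≥ 2) is available as
`transient_mode="z"`, but is not the default: cross-unit standardization
gives every unit a z profile that mirrors the population mix (a
nonencoding unit in a skewed population shows structure up to |z| ≈ 1.3,
overlapping weak genuine inhibition at |z| ≈ 1.0), so no z threshold
separates them, while the unit's own rate trace has a clean gap (noise
ceiling ≈ 0.5, weakest modulation ≈ 0.6 at gain 3).

Iterative k-means (50 k-means++ restarts per k, seeded) grows k from 2.
An iteration is accepted if it adds an encoding pattern or first isolates
a flat cluster; the search stops when a solution splits an existing
pattern — two modulated cluster profiles with cosine ≥ 0.9 between their
rate-deviation profiles — or adds nothing new.  A cluster is an encoding
pattern if its mean rate profile deviates ≥ 25% from session-mean firing
somewhere and holds ≥ 5% of units; smaller or flatter clusters are
labeled nonencoding, as are units farther from every centroid than the
97.5th percentile of within-cluster distances.  The reported k counts
encoding patterns only, matching the convention that nonencoding units
sit outside the k patterns.  Semantic labels (cue/reward ×
activated/inhibited, press-inhibited) come from window means of the
cluster's rate-deviation profile.

## Tensor component analysis

ALS updates the three factor matrices cyclically, each by solving its
linear least-squares subproblem via the Khatri-Rao/Gram identities with a
1e-12 ridge for degenerate Grams; the SSE trace is monotone and iteration
stops at a relative objective change below 1e-9 (default) or 500 sweeps.
After fitting, component scale is concentrated into the unit loadings
(trial and temporal columns unit-norm), resolving the CP scale ambiguity
so loadings are comparable across groups.  ALS is unconstrained by
default; a non-negativity projection on the unit mode is available.

Cross-run similarity matches components by maximum-weight bipartite
assignment (Hungarian) on the product of per-mode cosine congruences and
averages the matched products; it is invariant to permutation and to
sign/scale rebalancing (sign flips cancel in the three-mode product).

Rank selection fits `runs_per_candidate` (default 10) independently
seeded models per candidate; a candidate converges when mean pairwise
similarity ≥ 0.8.  Because a below-rank approximation is essentially
unique, under-ranked fits are also stable, so stability alone cannot
identify the model order: the selected rank is the smallest converging
candidate whose mean relative error is within 0.02 of the best error
among converging candidates.  On pure noise no candidate converges and
the result is "none".

The planted-assembly generator uses distinct Gaussian motifs per assembly
(cue bump 0.8 ± 0.45 s, cue dip 1.3 ± 0.7 s, reward bump 3.5 ± 1.0 s,
reward dip 5.0 ± 1.5 s), distinct trial trends (declining, growing, flat,
U-shaped) and non-negative unit loadings concentrated on disjoint unit
subsets with small cross-loadings.  Sign-flipped identical motifs would
make temporal factors collinear and break CP identifiability (Kruskal),
so "inhibited" assemblies get their own motif shape.  Noise is set from
the target SNR ‖signal‖/‖noise‖ (default 5).

## Demand economics

Fitting runs in log10 space (the standard base for this demand framework)
by bounded nonlinear least squares (Q0 ∈ (0, 10·max consumption],
α ∈ (0, 1]) from 5 deterministic starting points; zero-consumption bins
are dropped by default (or replaced by 0.1 rewards via a flag).  The
scale constant k defaults to the shared log10 range of the pooled
positive consumption ("shared_pooled"); "fixed" and "per_subject" are
available.  Note that the pooled-range k is strictly smaller than a
generating k whenever the largest observed price leaves consumption above
the model floor, so exact round-trips on synthetic data require the
"fixed" policy.

EV and Pmax are exact formula evaluations.  The closed-form Pmax
approximates the price at the interior peak of responding price·Q(price);
that peak exists only for k > e/ln10 ≈ 1.18 (below, the model's 10^−k
consumption floor makes response output eventually increasing and the
argmax is undefined).  Over k ∈ [1.5, 4], α ∈ [1e-4, 1e-1],
Q0 ∈ [5, 100] the approximation tracks the interior peak within 20%
(worst ≈ 8%; at k = 1.25 it reaches ≈ 23%).

## Bayesian encoding-bias inference

Model: y ~ Bernoulli(σ(β0 + β1·x)) with binary group x; β0 ~ N(0, 10²)
shared by null and alternative; β1 | g ~ N(0, g) with the compound
confluent hypergeometric prior on u = 1/(1+g),
p(u) ∝ u^(a/2−1)(1−u)^(b/2−1)e^(−su), which at the default (a, b, s) =
(0.5, 2, 0) is Beta(1/4, 1) — a heavy-tailed mixture placing substantial
mass on large g.  Because x is binary the likelihood reduces to 2×2
counts, and the u-integral affects only the marginal prior of β1, so the
marginal likelihoods are computed by (i) Gauss-Legendre quadrature over u
after the substitution u = v^(2/a), which removes the endpoint
singularity, then (ii) dense trapezoidal integration over (β0, β1) on
[−15, 15] × [−40, 40].  A brute-force 3-D grid integrator over
(β0, β1, u) is kept as an internal oracle; the two routes agree within a
fraction of a percent on random tables.  The credible interval is
equal-tailed 95% from the numerically marginalized posterior of β1.
Complete separation is flagged but inference proceeds (the prior
regularizes); the marginal then depends more on the β1 integration range,
which is why separated tables are not used in tolerance tests.
Antisymmetry under label swap holds to quadrature accuracy (~1e-3).

## Endophenotyping and prediction

PCA is of the correlation matrix (metrics have heterogeneous units), with
scores from the standardized data and a deterministic sign convention
(largest-magnitude loading positive).  Constant metrics raise an error
naming the metric.  The behavioral-prediction harness draws a seeded
80/20 split, fits an interchangeable regressor (default gradient-boosted
trees) on unit loadings, and reports held-out Pearson r; only the
harness (split, seeding, metric) is contract-tested, with a linear
regressor used where exact recoverability is asserted.  Real-data
correlations reported for such predictors are not reproducible from
synthetic data and are not asserted anywhere.

## Problem sizes and determinism

Planted-recovery checks use 150-unit food-like and 120-unit drug-like
sessions of 30 trials, 100 × 8 × 60 tensors, 5-price demand tables and
2×2 tables with n ≈ 100–200 — sizes comparable to the experiments the
pipeline is designed for, kept small enough that the full suite runs in
about a minute.  All generators and analyses are pure functions of
(spec, seed): identical seeds reproduce results bit-for-bit, and the
pipeline manifest records per-stage seeds derived from the master seed by
hashing.

## Known limitations

- The PR extension rule beyond trial 16 and the go/no-go
  pseudorandomization scheme are documented assumptions.
- Cross-unit z-scoring is within-session; pooling across sessions/animals
  would need a shared normalization record.
- The demand fit treats bins as independent observations; session-level
  autocorrelation is not modeled.
- The encoding-bias model is single-predictor; sex × treatment
  interactions are out of scope (group labels can encode any binary
  contrast).
- CP fitting is dense and CPU-only; tensors beyond ~10^7 entries will be
  slow.
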