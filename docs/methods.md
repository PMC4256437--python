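# Methods

## Tracks and preprocessing

A `TrackSequence` is one animal-observation bout: strictly increasing fix
times at a nominal interval Δ (20 s by default), planar coordinates in
meters, and a per-position behavior label from {walking, grazing,
resting, other, unlabeled}.  Geographic input is projected with a local
spherical transverse-Mercator projection centered on a reference point;
at paddock scale (distances well under 10 km) the scale distortion is
below 0.1%, far under GPS noise, so any conformal planar projection is
interchangeable here.

Gaps: a fix interval deviating from Δ by more than 25% splits the bout
into separate sequences, and segments shorter than 3 positions are
dropped.  Field protocols rarely document their missing-fix handling;
the 25% band keeps every retained step usable as a distance metric while
discarding nothing recoverable.

Labels are assigned from continuous-observation change-point logs with a
label-at-instant convention: a position carries the behavior active at
its timestamp (left-closed intervals).  The last change-point's behavior
extends to the end of the track unless an explicit observation end time
is supplied; positions outside the observed window are `unlabeled` and
excluded from training and from every accuracy denominator, as are
positions labeled `other`.

## Movement metrics

With H = horizon/Δ (default horizon 300 s), the distance catalog is
{cumulative, linear} × {backward, forward} × spans 1..H plus
{mean-cumulative, mean-linear} × spans 1..H, where the mean variants
average the backward and forward value at the same span.  At span 1 the
linear and cumulative distances coincide by definition (a single step is
its own straight line), so the three span-1 duplicates (backward linear,
forward linear, mean linear) are removed — by definitional identity, not
numeric comparison.  This yields 6H − 3 distance metrics: 87 at Δ = 20 s,
27 at Δ = 60 s.

The angle catalog is the raw absolute turning angle plus centered means
over windows of 3, 5, …, 2H − 1 positions: H metrics, i.e. 15 and 5.
The raw angle is included as the first member of the family (it is also
the sole angle predictor of the basic random-walk models); the largest
window, 29 positions at 20 s, spans ±4.7 min, the "up to five minutes
around each position" reading.  Turning angles are signed in (−π, π]
(positive = left turn) for the state-space model and absolute for
feature tables and kinematic summaries.

Boundary policy: a metric whose span reaches past either end of the
track is missing (NaN).  Rows with any missing predictor are excluded
from training; at prediction time they are reported as `unclassifiable`
and excluded from accuracy denominators, which keeps accuracy
well-defined without imputation.

## Balancing

Random undersampling (RUS) draws every class down to the smallest class
size without replacement.  Combined with a random forest it is applied
*inside* the forest — a fresh stratified draw per tree — not as a single
global undersample, so the ensemble still sees all majority-class rows.

SMOTE synthesizes minority rows as x + u·(x_nn − x) with u ~ U(0, 1) and
x_nn one of x's k = 5 nearest same-class neighbors (Euclidean distance,
the original SMOTE default), raising every minority class to the
majority count.  Features are not standardized before the neighbor
search by default (distances and angles live on comparable meter/radian
scales); a config switch would be the first thing to revisit for
predictors on wildly different scales.

## Classifiers

The random forest is an ensemble of CART trees (sklearn trees underneath)
with per-tree row sampling — bootstrap or per-tree RUS — sqrt(p) feature
subsetting and unlimited depth; 500 trees by default.  Tree counts and
depth limits are conventional defaults, not sensitive choices.  LDA uses
the pooled within-class covariance discriminant and refuses collinear
predictor sets, naming the offending columns.  The SVM is a one-vs-one
soft-margin machine with Gaussian RBF kernel, C = 1 and bandwidth from
the median heuristic on pairwise training distances (γ = 1/(2·median
squared distance), estimated on ≤ 500 subsampled rows).  The null model
draws states i.i.d. from the empirical class distribution, so each
state's expected accuracy equals its relative frequency.

Variable importance is per-class permutation importance computed from
each tree's out-of-bag rows (mean drop in class-specific accuracy when a
column is permuted), averaged over trees and then over 50 independent
forest realizations.

## State-space model

Three latent states with Weibull(k, λ) step lengths and wrapped
Cauchy(μ, ρ) turning angles, switching matrix Q, states identified by
ascending mean step λ·Γ(1+1/k): resting < grazing < walking.  One
observation pair (d, θ) per move; the turning angle of the first move of
a sequence is undefined and contributes the uniform density 1/2π, as do
angles at zero-length steps.  Step lengths are floored at 0.01 m before
Weibull evaluation because densities with k < 1 diverge at zero.

The sampler is blocked: (i) latent states by forward-filtering
backward-sampling (FFBS; numba-compiled inner loops), (ii) Q rows from
Dirichlet(1 + transition counts), (iii) emissions by random-walk
Metropolis — log-scale proposals with Gamma(0.01, 0.01) priors for k and
λ (the a·Δlog k term in the acceptance ratio combines the (a−1)·Δlog
prior with the +Δlog proposal Jacobian), wrapped proposals with a
uniform prior for μ, and plain proposals rejected outside [0, 1) for ρ.
Proposal scales adapt every 50 burn-in iterations toward 20–50%
acceptance and are frozen afterwards.  Label switching is resolved by
reordering states by mean step after every iteration.  The initial state
distribution is fixed uniform; with hundreds of observations it has no
leverage.  Default schedule: 3 chains × 700 iterations, 200 discarded,
1500 kept draws; chains start from jittered step-length quantiles.
Convergence is summarized by Gelman–Rubin R̂ per scalar parameter; any
R̂ > 1.1 flags the posterior as unconverged but is not fatal.

Decoding takes the most frequent state of each position across all kept
draws (ties to the lowest-index, i.e. slowest, state).  A sequence not
in the fit is decoded by running FFBS under every 5th kept draw's
parameters and taking the modal state — the held-out prediction rule
used in cross-validation.  Whether μ should be estimated or fixed at 0
is genuinely open; the default estimates it, with a `fix_mu` switch.
When ρ is small the angle distribution is near-uniform and μ is weakly
identified — the identified quantity is the first circular moment
ρ·e^{iμ}, which is what parameter-recovery checks compare.

## Evaluation

LOSO accuracy is reported both per sequence (with 50% and 95% quantile
intervals across sequences) and jointly over pooled scored positions;
the two differ whenever sequence lengths differ.  Folds whose training
sequences lack one of the three states are skipped with a warning.
Confusion matrices are row-normalized percentages over observed states.
Model comparisons use a paired two-sided t-test on per-sequence
accuracies; zero-variance difference vectors are reported as degenerate
rather than silently producing a p-value.

## Synthetic data

The generator is the generative twin of the state-space model with
heading persistence: the turning angle is added to the previous heading
(a correlated random walk), the standard step–turn reading.  Defaults
are the study conditions:

| parameter | value | why |
|---|---|---|
| Δ | 20 s | logging interval of the collars |
| mean speeds | 0.04 / 0.06 / 0.41 m/s (rest/graze/walk) | observed per-state means; Weibull mean = speed·Δ |
| Weibull shape k | 1.5 (all states) | right-skewed but unimodal step lengths |
| ρ | 0.1 / 0.4 / 0.8 | mean absolute turn angle ordering walking < grazing < resting |
| Q | 0.9·I + 0.1·1πᵀ, π = (0.25, 0.70, 0.05) | stationary law = observed 25/70/5% imbalance; dwell times ~3–11 min, activities lasting several minutes |
| GPS noise σ | 1.0 m per axis, i.i.d. | Rayleigh 95th pct 2.448·σ ≈ 2.45 m matches the stationary device test's 2.44 m relative error |

What the simulator does *not* emulate: temporally correlated GPS error
(real loggers drift; only the relative-error scale is matched),
systematic bias, terrain and paddock boundaries, herd interaction,
diurnal rhythm, and the bimodal within-grazing speed distribution seen
in real data.  Consequently, passing tests demonstrate that the
pipeline's machinery is correct under the model's own assumptions, not
that real cows are this easy: in particular, simulated walking (mean
step 8.2 m against a 1 m noise floor) is far more separable than field
walking, whose speed quantiles overlap grazing heavily.  This is why, on
synthetic data, undersampling equalizes resting and grazing accuracies
to within a point or two while walking stays near-perfect — a wider
residual spread between best- and worst-classified state than labeled
field data shows.

## Problem sizes

The test suite and examples run at deliberately modest sizes chosen to
exercise every code path at Monte-Carlo error small enough for the
stated tolerances: parameter recovery on a single 3000-position
noise-free bout with the default MCMC schedule; classifier comparisons
on ~10 bouts of 700 positions with 300-tree forests; moment and
frequency identities at 10⁴–10⁵ draws.  Real deployments would use the
full 500-tree default and all available sequences.
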