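# Methods

This note documents the models behind `sptmotion`, the defaults and the
reasoning for them, the numerical choices, and what the synthetic data do
and do not establish about real tracking data.

## Trajectory models

All trajectories are origin-anchored (r₀ = 0; every extracted feature is
translation-invariant, so nothing is lost), sampled at dt = 0.05 s for 100
frames, with positions in μm.

**Normal diffusion (ND).** Per-axis increments are i.i.d. N(0, 2D·dt), so
the 3D ensemble MSD is 6Dt. D is drawn per trajectory from
[0.1, 1.0] μm²/s — the range typical of protein-scale tracers in cells.

**Directed motion (DM).** A drift of speed coef·D (coef uniform in
[5, 20]) is superimposed on an ND component with the same D. The drift
direction performs a spherical random walk: azimuthal and polar angles
receive Gaussian increments of variance c·D·dt per frame. The two angles
share one variance constant c (default 1, configurable) because nothing
in the model distinguishes them; c = 0 recovers a perfectly straight
drift, used as a noise-free limit in tests.

**Anomalous subdiffusion (AD).** Each axis is an independent random-phase
Weierstrass–Mandelbrot series

W(t*) = Σₙ [cos φₙ − cos(γⁿ t* + φₙ)] / γ^(nα/2),  γ = √π,  n = −8..48,

with t* = 2πt/N and φₙ uniform on [0, 2π). The series is generated at
N = 2·N₀ points and subsampled at stride 2 — subsampling *positions*, not
alternate increments, because thinning increments destroys the long-range
anticorrelations that produce the t^α scaling (measured consequence: the
ensemble MSD exponent collapses to ~1 for every α). Each axis is scaled by
the closed-form phase-averaged increment standard deviation
√(Σₙ (1 − cos(γⁿδ))/γ^(nα)) to a per-step variance of 2D·dt^α; a
per-trajectory sample-std rescaling was rejected because it inflates
large-lag MSD by ~10%. With this construction the fitted ensemble log-log
MSD slope recovers α to 0.33/0.53/0.72 for α = 0.3/0.5/0.7 — a small
positive bias intrinsic to the truncated series, well inside the ±0.1
recovery tolerance. α is drawn from [0.3, 0.7]; only the WM model is
implemented (CTRW/FBM/ATTM would sample different physics and are out of
scope).

**Confined diffusion (CD).** The confinement radius is r = (D·B)^(1/3)
with B uniform in [1, 10] (the product interpretation of the radius
formula; the alternative D·B^(1/3) differs only in how the two sampled
parameters combine). Brownian sub-steps are taken at ddt = dt/100; any
sub-step ending farther than r from the start is rejected and redrawn
(cap 10 000 attempts, then a stall error reporting r and the step scale).
Every recorded frame therefore satisfies the bound exactly — the test
suite asserts zero violations over 10⁵ frames. The theoretical MSD is the
saturating form L(1 − exp(−6Dt/L)) with plateau L = 6r²/5, the mean
squared separation of two uniform points in a ball of radius r.

**Mixed motion (MM).** Segments of 20–50 frames, each simulated by one of
the four pure generators with freshly drawn parameters, concatenated with
positional continuity. Consecutive segments are forced to differ in type:
a "mixed" trajectory is by definition a sequence of transitions, and
allowing repeats would occasionally produce single-regime trajectories
labeled MM.

**Class mix.** 18% each of DM/ND/AD/CD and 28% MM, allocated by largest
remainder. The mix gives switching behavior substantial weight without
letting any pure class dominate. All of the above ranges are defaults of
`SimulationConfig`, chosen once as plausible study conditions and exposed
so users with different experimental regimes can match them.

## Segmentation and features

Windows are 29 frames (odd, so the center frame is unambiguous), sliding
with step 1 — maximal overlap maximizes training data and temporal
resolution of regime switches; the step is configurable. A window is
labeled by its center frame's ground truth, so classification accuracy is
the fraction of windows whose center label is recovered. Trajectories
shorter than the window are skipped with a warning rather than an error,
so short extracted tracks never abort a batch.

The 14 features are computed from the window alone (re-anchored to its
first position) and are invariant to rigid rotation and translation,
verified numerically to 1e-9. MSD-derived features (α fit, average MSD
ratio, Gaussianity) use lags 1..⌊W/2⌋ = 14, balancing lag range against
the noise of time-averaging few pairs. Dimension-dependent constants
switch with the 2D/3D flag: the Gaussianity denominator is 5/3 (3D) or 2
(2D), and short-lag diffusivity estimates use MSD₁/(2d·dt).

Numerical guards, chosen so the feature table never contains non-finite
values: Katz fractal dimension capped at 4 (the d→L log singularity);
asymmetry capped at 10 (collinear windows); degenerate (stationary)
windows fall back to jump length 0, trappedness 1, fractal dimension 1,
and 0 elsewhere. Kurtosis is the population fourth standardized moment of
positions projected on the dominant gyration-tensor eigenvector (not
excess, not bias-corrected). Trappedness keeps the literature coefficients
1 − exp(0.2048 − 0.25117·D̂T/r₀²), a fit originally derived for 2D discs;
no 3D refit exists, which is a documented limitation. Velocity
autocorrelation is normalized with matched means (mean dot product over
mean step energy) so a perfect zigzag scores exactly −1. The angular
Gaussianity index — the moment ratio ⟨θ⁴⟩/(3⟨θ²⟩²) − 1 of consecutive-step
turning angles — is this package's own concrete construction of a
loosely specified quantity and is isolated behind one function so it can
be swapped without touching the pipeline.

Known estimator bias: the per-window time-averaged Gaussianity at W = 29
carries a finite-sample bias of about −0.11 for ideal Brownian windows
(the ensemble mean sits just below zero, not at zero). Tests assert the
measured behavior rather than the idealized zero.

## Feature selection

Three rankers run independently on the training table; the reduced set is
the unweighted union of each ranker's top 3.

* **mRMR**: greedy forward selection on the MID (difference) criterion,
  mutual information estimated on 10 equal-frequency bins. Constant
  features have zero relevance and rank last.
* **ReliefF**: Kononenko's multiclass weights with k = 10 neighbors,
  prior-weighted miss contributions, min-max normalized features; the
  instance sample is seeded and configurable (all instances by default,
  subsampled at study scale).
* **NCA**: diagonal-weighted neighborhood component analysis — squared
  distance Σ w_f²Δ_f², leave-one-out softmax objective, L2 penalty
  defaulting to 1/n — optimized with Adam-style adaptive gradient ascent
  (120 iterations; plain gradient ascent diverges under strong
  regularization). Features are z-scored first; rows are subsampled
  (stratified, seeded) above 2000 because the objective is quadratic in n.

## Classifiers

All trees are CART with Gini impurity and axis-aligned splits
(scikit-learn). "Bagged trees" is bootstrap aggregation with all features
available at each split; "random forest" additionally samples √p features
per split; "boosted trees" is SAMME adaptive boosting of depth-3 trees;
plus a single-tree baseline. Majority votes are aggregated across trees
with ties broken by the fixed canonical order DM < ND < AD < CD. The
baseline configuration is 100 trees with depth cap 10.

Two splitting protocols exist deliberately. The library default groups
all windows of one trajectory on the same side of any split or CV fold
(stratified by trajectory class) — step-1 windows overlap by 28 of 29
frames, so window-level splits leak near-duplicates and flatter the
accuracy. The study protocol (`sptmotion.study`, the acceptance script)
uses window-level 90/10 splits and folds, which is how the reference
numbers are defined; measured at 600 trajectories the difference is
74.9% (grouped) vs 80.9% (window-level) test accuracy. Out-of-bag error
aggregates, per training sample, only votes of trees whose bootstrap
excluded it; samples never out of bag are skipped and counted.

## Hyperparameter tuning

The search space is learning cycles (number of bagged trees) ∈ [150, 500]
and minimum leaf size ∈ [20, 50]; tuned models use the leaf size as their
regularizer and no depth cap. The objective is seeded 5-fold CV
misclassification loss. Bayesian optimization uses a Matérn-5/2 Gaussian
process on the unit-scaled box with expected improvement evaluated
exhaustively over the 351×31 integer grid, a 10-point jittered
latin-hypercube initial design, and a 30-evaluation budget (the loss
trace plateaus well before that); failed evaluations are recorded as NaN
and ignored by the surrogate. Random search samples uniformly with
replacement (25 draws at study scale). On a smooth benchmark with a known
grid optimum the Bayesian search recovers the exact optimum and beats
matched-budget random search in 20/20 seeded repetitions. No early
stopping: bagging trains trees independently, so there is no sequential
signal to stop on.

## Study scale and runtimes

The reference study (`run_reference_study`) uses 1000 trajectories × 100
frames → 72 000 windows, window-level 90/10 split. The tuning objective is
evaluated on a stratified 2000-window subsample of the training split
(each evaluation trains up to 2500 trees across folds); tuned
configurations are refitted on a 30 000-window subsample; one-vs-rest
permutation importances use a 20 000-window subsample, 100 trees, 2
permutation repeats. These sizes keep a complete run — simulation through
tuning and importances — around 15 minutes on a single CPU while leaving
the statistical conclusions stable; every size is a `StudyScale` field,
so a full-scale run (5000 trajectories, larger subsets) is one argument
away.

## What the synthetic data establish — and what they do not

The generator reproduces the *kinematics* of the four regimes (step
distributions, MSD laws, confinement geometry, regime switching). It does
not model localization error, motion blur, fluorophore blinking, drift of
the stage, or tracking/linking mistakes; trajectories are evenly sampled
with no gaps. Classification accuracies measured here are therefore upper
bounds for real microscopy data, and feature rankings can shift when
localization noise floors the short-lag MSD. The relative difficulty
structure is expected to transfer: directed motion is easy at any
realistic noise level, and normal vs weakly confined diffusion is
intrinsically ambiguous at a 29-frame horizon because a particle that has
not reached its boundary is statistically Brownian — visible here as the
dominant ND↔CD confusion. Which features dominate a ranking depends on
the simulated parameter ranges: under these defaults geometric features
(fractal dimension, jump length, velocity autocorrelation) carry most of
the class information, while moment-shape features (kurtosis,
Gaussianity) separate classes only weakly.
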