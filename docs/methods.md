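# Methods

## Model

The decoder is logistic regression on the voxel space with the elastic-net
penalty:

J(w, b) = Σᵢ [log(1 + exp(ηᵢ)) − yᵢηᵢ] + λ1‖w‖₁ + (λ2/2)‖w‖₂²,
η = Xw + b,

with labels y ∈ {0,1} (standard/target), an unpenalized intercept, and the
negative log-likelihood summed (not averaged) over trials, so λ1 and λ2
share the likelihood's scale. Features are z-scored per training split by
default (means/SDs from the training trials are applied to that split's
held-out trials); this is switchable but recommended, since the l1 penalty
is not scale-invariant.

### Regularization grid

The default grid is 11 log-spaced λ2 values × a 100-point log-spaced
descending λ1 path (1,100 points). The path starts at
λ_max = maxⱼ |xⱼ·(ȳ − y)| — the smallest λ1 whose solution is the zero map —
and ends at `lambda1_ratio`·λ_max (default 0.1; a ratio much below ~0.05 at
p ≫ n mostly adds near-saturated models). λ2 spans 10⁻³·λ_max to λ_max.
The grid is computed once per dataset from the full data and shared by all
resamples and permutations, so that grid points are comparable across them.

### Solver

A proximal-Newton (IRLS + coordinate-descent) scheme:

1. restricted solve on the current active set: quadratic approximation at
   the current iterate, minimized by cyclic coordinate descent with
   soft-thresholding, intercept unpenalized; a step-halving line search
   guarantees the penalized objective never increases (the per-iteration
   objective history is exposed and asserted monotone in the tests);
2. full KKT sweep over all p features; coordinates violating the
   subgradient conditions are screened in and step 1 repeats.

Convergence requires the KKT residual of the true objective below
`kkt_tol` (default 10⁻⁴ × max(1, λ_max), i.e. four decades below the
gradient scale of the data); the relative objective-change tolerance is
10⁻⁷ with a budget of 10⁴ coordinate passes, and a solve that cannot reach
the tolerance raises an error carrying iterate diagnostics rather than
returning silently. IRLS weights are floored at 10⁻⁵ and linear predictors
clipped at ±30 for separable data.

Families over the grid are trained sequentially with two standard path
accelerations that do not change the estimator: warm starts down each λ1
path, and sequential strong-rule screening (|gⱼ| > 2λ1,new − λ1,old at the
previous solution) to seed the active set. Warm-started path solutions are
verified against cold starts to 10⁻⁶ in objective in the tests. The family
trainer works in single precision by default — the gradient sweeps are
memory-bandwidth-bound and the KKT tolerance sits far above float32
rounding — with a float64 switch used wherever tests check tight numerical
identities.

### Voxel cap

The number of voxels a decoder may use is capped (default 1,000). When a
fit's support exceeds the cap, the fit is marked capped, the rest of that
λ1 path is skipped for that resample, and the affected grid points are
flagged; capped points report no statistics and are ineligible for model
selection. Truncation is the cleanest rule consistent with a hard cap: a
partially-capped grid point would mix estimators across resamples.

## Reproducibility statistics

From the B maps of one grid point (unselected entries counted as weight 0):
v_i = (#maps with w_i ≠ 0)/B, μ_i and se_i are the mean and the sample
standard deviation (ddof = 1) of the B weight estimates — the spread of the
resampling distribution, with no √B division — and z_i = μ_i/se_i.

ψ_sp = Σv_i²/Σv_i and ψ_|z| = Σv_i|z_i|/Σv_i. Both are v-weighted means
normalized by n̄ = Σv_i, the mean number of selected voxels. ψ_sp is
exactly the expectation of v over the two-stage draw "pick a map uniformly,
pick one of its selected voxels uniformly" when all maps select equally
many voxels (verified by exhaustive enumeration in the tests); with unequal
support sizes the closed form weights maps by support size, and we adopt
the closed form as the definition. ψ_sp ∈ (0, 1] with equality iff every
v_i ∈ {0, 1}; ψ_|z| ≥ 0 and unbounded. A voxel with v_i > 0 but se_i = 0
(identical nonzero weight in every map) gets a +∞ z sentinel; ψ_|z|
excludes such voxels with a warning by default (an ε-floor alternative is
available), while the voxel-level test treats an infinite observed |z| as
exceeding every finite null value.

A_z is computed per cross-validation repeat by pooling that repeat's
held-out decision scores into one ROC (Mann–Whitney with ties counted
half), then averaged over repeats; per-fold averaging is available as an
option. Pooling within a repeat keeps A_z defined even when a single fold's
test set lacks one class.

## Model selection

Pareto filtering, the 2-D convex hull (for visualization), and the three
strategies operate on eligible (non-capped, non-empty) grid points. JointSP
minimizes the unweighted Euclidean distance to (ψ_sp, A_z) = (1, 1); both
axes already live in [0, 1], and configurable axis weights are exposed. Ties
are broken toward larger ψ_sp, then larger λ1 (the sparser model), then the
lowest grid index — deterministic, and the ψ-favoring tie-break is what
makes the ordering ψ_sp(JointSP) ≥ ψ_sp(MaxAz), A_z(MaxAz) ≥ A_z(JointSP)
a theorem rather than a tendency (asserted on every run in the tests).

## Permutation significance

Labels are permuted uniformly (class counts preserved; features untouched)
and the full grid is retrained per permutation on the same CV partitions.
Summary-level nulls take the maximum of each statistic over eligible grid
points, one value per permutation, pooled across permutations (and
subjects, when given). One-tailed thresholds are the order statistic
x₍⌈(1−α)(m+1)⌉₎ of the sorted null sample — the convention under which a
null of (1..100)/100 yields 0.96 at α = 0.05; when ⌈(1−α)(m+1)⌉ > m the
threshold clips to the sample maximum with a warning.

Voxel-level nulls assume exchangeability of voxel statistics under the
null (the classifier has no spatial prior) and pool, from each
permutation's JointSP-selected model, the v_i and finite |z_i| of voxels
with v_i > 0. Observed statistics become add-one one-tailed p-values
p = (1 + #{null ≥ obs})/(1 + m) — never zero from finite permutations, ties
counted conservatively — and are thresholded by Benjamini–Hochberg:
k = max{k : p₍ₖ₎ ≤ (k/N)α} over the N tested voxels, rejecting the k
smallest.

At desk scale (p ≈ 2000, n ≈ 300, B = 50 CV resamples) the pooled null of
selection probabilities acquires a sizable atom at v = 1: under a permuted
labeling the resamples still share ~90% of their trials, so the best few
noise voxels are re-selected in every resample. Observed v = 1 then cannot
beat the null atom and the sp-based FDR set can be empty while the z-based
set localizes the signal cleanly (weight *values* of noise voxels are far
less stable than their selection). Both analyses are computed and reported;
recovery in the acceptance checks is scored on their union. At realistic
voxel counts (p ≈ 5×10⁴) the atom thins out because the identity of the
top noise voxels varies across resamples.

## Synthetic data

The trial-wise generator draws labels i.i.d. Bernoulli(0.2) — the rare
target rate of an oddball design — and activations Normal(0, σ²) with a
class-1 mean shift of d·σ at the signal voxels (default d = 1.0, σ = 1).
Signal voxels form face-connected blobs grown by random accretion on the
3-D grid, kept mutually non-adjacent so the support has exactly the
requested number of components. Default sizes (300 trials, 2,000 voxels,
50 signal voxels in 5 clusters) are a desk-scale version of an
event-related study (hundreds of trials, tens of thousands of voxels);
every field is configurable up to realistic scale.

The time-series generator places onsets with a uniform 2–3 s jittered
inter-trial interval after a 200 ms stimulus, at TR = 2 s, and superimposes
HRF responses linearly: series = Σₜ amplitudeₜ · (δ(onsetₜ) ⊛ HRF) + noise.
The canonical HRF is a double gamma with mode 6 s, undershoot mode 16 s,
peak:undershoot ratio 6, length 32 s, unit peak (all configurable). Events
are impulses by default; a boxcar of the stimulus duration is available.
Noise is i.i.d. Gaussian with an optional AR(1) knob — real BOLD noise is
autocorrelated and spatially smooth, and neither property is emulated by
default, so passing tests demonstrate correctness of the machinery on data
that satisfy the model's assumptions, not performance on real fMRI.

## LS-S deconvolution

For each trial, every voxel's series is regressed on [signal, noise,
intercept]: the trial's own HRF-convolved onset impulse, the superposition
of all other trials', and an unpenalized constant (the noise column is
dropped in a single-trial design, where it is identically zero;
user-supplied confound columns can be appended). The signal coefficient is
the trial's activation. Only timing enters, never labels, so the step needs
no cross-validation wrapping — verified by a label-invariance test. Exact
recovery of generating amplitudes holds when the generating process lies in
the per-trial design span (non-overlapping responses, two trials, or
amplitudes constant across trials); with trial-varying amplitudes under
overlap, LS-S is the usual variance/bias compromise and recovery is
approximate by design. Rank-deficient designs (e.g. duplicate onsets) raise
an error naming the trial. Drift regressors are intentionally absent —
high-pass filtering is assumed upstream.

## Group aggregation

Per-subject binary significance masks on a shared grid are summed; the
suprathreshold set is decomposed into connected components (26-connectivity
default; 18/6 available). Each cluster reports its size, the maximum
per-voxel subject count, the number of distinct subjects contributing at
least one voxel (computed from the per-subject masks, not the counts), and
its centroid. Spatial normalization to the common grid is an input
requirement, not performed here.

## Problem sizes used in the checks

The automated checks run the full pipeline at n = 300 trials × p = 2,000
voxels with a 10 × 10 grid, 10-fold × 5-repeat CV (B = 50) and 20
permutations per dataset, across ten seeds, for signal recovery; and 50
pure-noise replicates at n = 200 × p = 500 with a 6 × 6 grid, B = 20 and
10 permutations for null calibration. These sizes were chosen so a complete
run stays desk-scale on one CPU while every stage — grid training,
permutation nulls, voxel FDR — runs in its full form; `scripts/acceptance.py`
uses the same conditions with three signal and ten null replicates.

## Known limitations

* Reported empirical thresholds depend on the permutation count; with 20
  permutations the p < 0.01 summary threshold clips to the null maximum
  (warned).
* The λ1 path ratio and λ2 range are declared defaults, not estimated from
  data; extremely weak signals may need a deeper path.
* Exchangeability of voxel nulls ignores spatial correlation; on spatially
  smooth real data the pooled voxel null is an approximation.
* The synthetic generator's noise is white in time and space; conclusions
  about real-data performance require real data.
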