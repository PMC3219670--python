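# Methods

## Model and fitting

Intensities x_i (single channel; the internal formulas keep the vector/
matrix form so multichannel features work unchanged) follow an M-component
Gaussian mixture p(x_i|θ) = Σ_j α_j N(x_i; μ_j, Σ_j) with Σ_j α_j = 1.
Plain EM alternates the Bayes-rule E-step with the standard weight/mean/
covariance M-step until the relative change of the log-likelihood drops
below `tol` (default 1e-6, at most 200 iterations).  All densities are
evaluated in log space and responsibilities are normalized by log-sum-exp,
so distant outliers never underflow to an error.

The spatial variant replaces every occurrence of the pixel density
p_j(x_i) with the blend (1−β)·p_j(x_i) + β·p_j(x̄_i), where x̄ is the
neighbourhood-average image computed once before the iterations start:

- objective: Σ_i log Σ_j α_j[(1−β)p_j(x_i) + β p_j(x̄_i)]
- E-step: posteriors proportional to α_j times the blended density
- mean update: responsibility-weighted average of (1−β)x_i + βx̄_i
- covariance update: responsibility-weighted average of
  d(x_i) + β·d(x̄_i), d(x) = (x−μ)(x−μ)ᵀ, divided by the responsibility
  mass.

The covariance numerator is *not* a convex combination — the β-term is
added on top, so fitted variances are inflated by roughly (1+β) relative
to a consistent estimator.  This asymmetric form is the method's defining
update rule and is kept as the default; `normalize_covariance=True`
divides by (1+β) for a variance-consistent variant.  Since β ≤ 0.5 the
inflation is at most ~9% in standard deviation and does not move the
means.

Both fitters share one engine: with β = 0 the spatial terms are skipped
entirely (not multiplied by zero), so the spatial fit at β = 0 is
bit-identical to plain EM — an invariant the tests assert on every
fixture.

### Convergence of the spatial loop

The blended M-step is not a proven ascent step on the blended objective.
In practice the objective is monotone on all our fixtures, but the fitter
additionally stops if the objective decreases on two consecutive
iterations and then restores the best parameters seen.  Plain EM keeps
its usual monotonicity guarantee, asserted with 1e-9 slack.

### Initialization and degeneracies

Default initialization is k-means on the intensities (10 restarts, seeded,
components sorted by ascending mean, per-cluster variances); a quantile
initialization (means at the (2j+1)/2M quantiles, global variance, uniform
weights) is available, and explicit parameters can be passed.  Variances
are floored at 1e-8 on the normalized scale after every M-step to prevent
singular collapse onto repeated values.  A component whose responsibility
mass vanishes entirely is re-seeded at the pixel with the lowest maximum
responsibility (the point the model currently explains worst), given
weight 1/N and the global data covariance; the event is logged.  Ties in
the final argmax labelling go to the lowest component index.

### Intensity normalization

Fitting happens on min-max [0,1]-normalized intensities; fitted means and
covariances are mapped back to the input scale in the returned result.
Hard labels are invariant under this affine map for plain EM, and for the
spatial variant it pins β to a dimensionless scale.  The log-likelihood
trace is reported on the normalized scale.

## The spatial weight β

Magnitude-MRI background contains no signal, so its Rician noise is
Rayleigh; the MLE of the Rayleigh scale² from n background observations
O_i is σ̂² = (1/2n)ΣO_i², which equals the per-channel Gaussian noise
variance.  In auto mode β is set to σ̂ — the noise *level* on the
normalized intensity scale — clamped to [0, 0.5] so the pixel's own
evidence always dominates.  Whether β should equal the noise level σ or
the noise variance σ² is a genuine modelling choice; we ship both
(`beta_mode="std"` default, `"variance"` optional) and default to σ
because on unit-normalized intensities σ² is 0.001–0.008 at realistic
(1–9%) noise levels, a weight too small for the spatial term to matter,
whereas σ ≈ 0.03–0.09 reproduces the two behaviours the method is known
for: a clear Dice advantage over plain EM above ~5% noise, and a
similarity index that degrades as the window grows on fine structure.

Background pixels come from an explicit mask when one is available (in
the phantom experiments the ground-truth background is used: thresholding
a noisy image at 5% of max keeps only the lower tail of the Rayleigh
distribution and underestimates σ² several-fold).  Without a mask, pixels
at or below `background_threshold` (default 0.05) × max intensity are
used; with no qualifying pixels at all, β falls back to 0.1 and the event
is logged.  Explicit β always wins and skips estimation.

## Neighbourhood average

x̄ is the windowed mean (default 3×3) around each pixel, excluding the
center pixel itself, with edge-including reflection padding (constant-zero
padding optional).  Exclusion of the center and reflection at borders are
the literal reading of "average of the neighbours" that avoids biasing
border pixels dark.  Windows are legal while the padding half-width is
smaller than the image extent (so a 3-window on a 2×2 image is fine); the
window must be odd.  3-D volumes are averaged slice-wise with a 2-D window
by default, matching per-slice processing of MRI stacks; a volumetric
window is a config switch.  The average is computed by a uniform filter in
O(N), once, so the spatial iterations cost the same as plain EM.

## Phantoms

The generator emulates piecewise-constant multi-tissue images: a label
geometry (equal-area nested annuli with background outside; seeded Voronoi
blobs; fine stripes cycling through all classes, width 3 by default), then
i.i.d. Gaussian intensities per class, clipped at zero.  The standard
test-bench configuration is 64×64 with four labels — background (mean 0,
spread 0) plus three tissues at means 0.3/0.6/0.9 with spread 0.02 —
echoing T1 contrast between CSF, grey matter and white matter.  Rician
noise is applied as out = √((m+g₁)² + g₂²) with g₁,g₂ ~ N(0, σ²) and
σ = level% × max intensity (the convention of the public simulated-MRI
repositories); this is identical in law to Rice sampling and exactly
Rayleigh in the background.  The striped geometry exists specifically to
expose window-size blurring.

What the phantoms do *not* model: anatomy, partial-volume voxels at class
boundaries, intensity in-homogeneity (bias fields), and spatially
correlated noise.  Passing tests therefore demonstrate the estimator and
algorithm properties (reduction, monotonicity, recovery, noise trends),
not clinical segmentation accuracy on real scans.

## Evaluation protocol

Predicted clusters are matched one-to-one to truth classes by maximum
total overlap (exhaustive over assignments up to six classes with
lowest-index tie-breaks, Hungarian beyond).  With background exclusion on
— the default, as in the usual brain-MRI protocol — the truth background
class and the predicted cluster with the lowest mean grey value are
removed before matching.  Per class: ρ = 2|X∩Y|/(|X|+|Y|),
r_fp = (|Y|−|X∩Y|)/|X|, r_fn = (|X|−|X∩Y|)/|X| (both ratios normalized by
the truth size |X|, as the index is conventionally printed), and Jaccard
J = |X∩Y|/|X∪Y|; ρ = 2J/(1+J) exactly.  Volume averages are unweighted
means over scored classes; a truth class with no matched cluster scores
ρ = 0, r_fn = 1 and is flagged, as is an empty truth class (skipped).

## Refinement

`ClusterTree.from_labels` relabels the initial clusters 1..K (K ≤ 9) so
that the decimal child-naming scheme (children of c are c·10+1, c·10+2,
ordered dark→bright) never collides.  A split re-fits only the selected
cluster's pixels with a two-component mixture (quantile-initialized,
seeded; optionally the spatially blended variant using the full-image
neighbourhood average restricted to the cluster) and touches no other
pixel.  Merging maps every leaf to a tissue id and errors on any
unassigned leaf by name.  Splitting then merging both children back to
the parent's tissue restores the input exactly.

## Problem sizes and determinism

The test suite and the acceptance script run everything on 64×64 (trend
experiments, 10 seeds per condition) and 32×32 (reduction checks)
phantoms with M ≤ 4 — sizes at which each EM fit takes tens of
milliseconds, so the whole bench completes in well under a minute while
every per-class occupancy still exceeds the 1% floor.  All randomness
flows through explicit integer seeds (NumPy `default_rng`, seeded
k-means), and CLI label outputs are byte-reproducible for a fixed seed.

## Known limitations

- The as-printed covariance update inflates variances by ~(1+β); use
  `normalize_covariance` when calibrated variances matter.
- Threshold-based background extraction on noisy images truncates the
  Rayleigh tail and biases σ̂² low; prefer an explicit mask when one
  exists.
- Auto-β assumes the image *has* background; on cropped images without
  any dark region the fallback (β = 0.1) is a blunt default.
- Model order M is user-specified; there is no model selection.
- No bias-field correction: strong in-homogeneity violates the
  per-class-Gaussian assumption and should be corrected upstream.
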