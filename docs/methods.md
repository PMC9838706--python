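# Methods

## The mediation system

For age `A` (years), a mediator `B` (a per-voxel or regional
demand-response measure in arbitrary ΔBOLD-like units), and an IQ-like
outcome `C`, four OLS regressions are fitted: the total effect
(`C ~ A`), the direct-plus-mediator model (`C ~ B + A`), the age effect
on the mediator (`B ~ A`), and a moderation check adding an `A×B`
product (`C ~ B + A + A×B`). The indirect effect `ab = a·b` equals
`c − c'` identically for OLS on a common sample; the identity is
asserted at 1e-10 relative tolerance on every fit and bootstrap
resample, which catches sample-alignment bugs essentially for free.

The product term in the fourth equation uses mean-centered `A` and `B`.
Centering is a choice, not a mathematical necessity: it leaves the `d`
t-test and its Cohen's f² = (R²_full − R²_reduced)/(1 − R²_full)
invariant while improving the conditioning of the normal equations.

Mediation is tested by joint significance: a two-tailed test of `a` and
a one-tailed test that `b` is on the side of zero *opposite* to `a`
(consistent mediation), with conjunction p = max of the two. This is
conservative relative to product-of-coefficients tests under the
both-null hypothesis but controls type I error when only one path is
null — the property the acceptance suite checks by simulation (rejection
≤ α + 2 Monte Carlo SEs under either single null at n = 250, 2000
replicates). If `a` is exactly zero the directional test is undefined
and the two-tailed p is returned with a flag.

### Bias-corrected bootstrap

Whole subjects are resampled with replacement (case resampling) and the
full system refit per resample; the BC (no acceleration) interval places
its bounds at the Φ(2z₀ ± z_{1−α/2}) percentiles, with z₀ estimated from
the fraction of resamples below the point estimate. A single
implementation backs the indirect-effect CI, the moderated-mediation
compound-path p (by interval inversion), and the LiNGAM cluster
bootstrap. Resamples in which the system is unidentifiable — constant
`A` or `B`, or `B` exactly collinear with `A` (possible when a small
resample collapses onto two distinct subjects) — are redrawn and
counted; a redraw rate above 1% triggers a warning rather than an error,
since it is expected for n ≲ 10. The default resample count is 15,000;
simulation-based tests use fewer, which affects only Monte Carlo noise
in the interval endpoints. Measured coverage for `ab` at nominal 95% is
~94% (n = 250, 500 replicates × 2000 resamples).

## Voxel-wise hierarchy

Per voxel, fits use only the subjects with data at that voxel; voxels
below the availability floor (default 100 subjects) are excluded before
any testing and never re-enter. The selection stages are: (1)
Benjamini–Hochberg FDR (q = 0.05) on the two-tailed `a` p-values across
all floor-passing voxels; (2) removal of voxels showing moderation of
the direct age effect (f² ≥ 0.02 or p(d) ≤ 0.05); (3) BH FDR on the
conjunction p within the survivors. FDR pools are per-stage, mirroring
the hierarchy rather than one global correction. "Summary" voxels
additionally require complete data and a positive mean group contrast
(one-sample Cohen's d = mean/SD over available subjects), and their
mask-aware mean defines the summary mediator used by all downstream
diagnostics. The hot path solves the per-voxel normal equations in
batch (3×3 and 4×4 solves over sufficient statistics); equality with
column-wise single fits is tested.

## Spatial statistics

Correlating two statistic maps voxel-wise inflates significance under
smoothness. The remedy: build the eigenbasis of the doubly centered
proximity matrix `W_ij = 1 − (d_ij/d_max)³` (zero diagonal) over the
analyzed voxels' world coordinates, and generate surrogates of one map
by flipping the signs of its spectral coefficients independently (the
"singleton" scheme). Because sign flips preserve each coefficient's
power, every surrogate has *exactly* the source map's Moran's I
(I = (n/ΣW)·x̃ᵀWx̃/x̃ᵀx̃; the centered matrix changes nothing here since
x̃ ⊥ 1) and marginal variance; the permutation p is
(1 + #{|r_null| ≥ |r_obs|})/(1 + n_perm), default 10,000 permutations.
Calibration is verified by simulation (uniform p for independent smooth
maps where a naive value permutation rejects an order of magnitude too
often). The cubic kernel is one standard Moran-eigenvector choice and is
exposed as a parameter; the test's validity comes from the surrogate
contract, not the kernel. Voxel sets beyond a configurable cap (default
5000) are randomly subsampled before the dense eigendecomposition, with
the subsample indices carried on the basis.

Two notes on the eigenbasis. The nontrivial eigenvectors of the doubly
centered matrix are themselves centered (orthogonal to the constant
vector), which is the invariant the tests assert; the *mean eigenvalue*
is −ΣW/n² ≠ 0 for any zero-diagonal kernel, so no zero-trace
normalization is applied — keeping raw eigenvalues preserves the exact
identity I(v_k) = (n/ΣW)·λ_k used as an oracle. Degenerate eigenvalues
(e.g. symmetric point sets) make individual eigenvectors non-unique;
comparisons are then between eigenspace projectors.

The watershed partitioner floods catchment basins from local minima
(plateau minima merged, 26-connectivity by default, face connectivity
optional) using the scikit-image watershed with labeled-minima markers;
labels are contiguous from 1 and partition the mask exactly. Cluster
counts depend on connectivity and map roughness and are not a
reproducibility target.

## LOVE sensitivity analysis

The question: how strong must an unmodeled confounder `U` of the
mediator–outcome relation be to explain the observed mediation? Working
in the space of residuals on age (age is treated as exogenous; a
marginal variant is available), the adjusted slope at hypothetical
partial correlations (r_UM, r_UY) is the coefficient `B` would receive
in a regression of `C` on `B` and `U`:

    b_adj = (r_BC − r_UM·r_UY)/(1 − r_UM²) · (s_C/s_B),

so `ab_adj = a·b_adj` vanishes exactly on the hyperbola
r_UM·r_UY = r_BC. The symmetric threshold r* (both correlations equal)
is therefore √|r_BC|; the zero contour also yields the smallest single
coordinate at least one correlation must reach, and the smallest
average, mirroring the two-number summary conventional for this
analysis. Grid points whose implied (U, B, C) correlation matrix is not
positive semi-definite are flagged infeasible and excluded from the
contour. One subtlety, verified against the explicit-covariate oracle:
along the axis r_UY = 0 the adjustment does *not* return the unadjusted
`b` (conditioning on a variable correlated with `B` rescales its
coefficient by 1/(1 − r_UM²)); only the origin reproduces `ab` exactly.
The confounder injector constructs `U` in the sample space spanned by
the observed variables (Gram–Schmidt plus orthogonalized noise), so
realized sample correlations hit their targets to machine precision and
infeasible target pairs are detected exactly.

## Causal direction (ICA-LiNGAM)

With standardized variables and at most one Gaussian structural error,
`X = BX + E` is identified by ICA: the unmixing matrix is a row-permuted,
row-scaled `I − B`. The estimator uses fixed-point negentropy ICA
(deflation, logcosh) with 5 restarts (best by negentropy; failure of all
restarts raises an error carrying the seeds tried), the row permutation
minimizing Σ1/|W_ii| (exhaustive, fine for ≤ 6 variables), rescaling to
a unit diagonal, then pruning of the ⌈m(m+1)/2⌉ smallest entries of `B`
(plus anything below 1e-3) and, if needed, further smallest entries
until some variable ordering makes `B` strictly lower triangular —
otherwise the estimate is flagged non-triangular. Given the recovered
order, the lower triangle is re-estimated by sequential least squares on
the standardized data, the final covariance-based step of the reference
implementation of this algorithm; without it, raw ICA coefficient noise
(~0.05–0.08 at n = 1000) would dominate null-edge estimates.
Directionality of a pair is |coefficient in the hypothesized direction|
− |reverse|; exactly one of the two is nonzero in a triangular solution.
Gaussian errors make the direction unidentifiable, and the test suite
asserts the *failure* of recovery in that case rather than pretending
otherwise.

Cluster mode: mediating voxels are split by watershed, each cluster's
mask-aware mean mediator refits the 3-variable model per bootstrap
resample of subjects, clusters are discarded when any undirected
coefficient (the nonzero one of each pair, read ignoring direction)
disagrees in sign with the all-voxel reference or when the fit is
non-triangular, and the resample's directionality is the mean over
retained clusters; BC intervals are taken across resamples, with
discard and empty-resample rates reported.

## Moderated mediation

With a standardized moderator `Z` and mean-centered `A`, `B`:

    stage 1:  B ~ A + Z + A×Z
    stage 2:  C ~ B + A + Z + B×Z + A×Z

The `A×Z` term is included in stage 2 so direct-path moderation is
estimable alongside `b` moderation; a `B×A` term is not (the pipeline
has already screened for moderation by age). Simple paths are evaluated
at Z = ±1 SD and each Δ is the change across 2 SDs (Δa = 2·a_AZ, etc.).
Single-path deltas use the parametric t test of the interaction
coefficient; the compound Δ(ab) and Δ(ab + c′) use the shared BC
bootstrap with full per-resample re-standardization. Rows with a missing
moderator are dropped listwise and the usable N reported. A moderator
can be residualized on the others (then re-standardized) to isolate its
unique contribution.

## Diagnostics and motion control

* RESET: the base design is augmented with powers 2–4 of the
  standardized fitted values and the three added terms are F-tested
  (numerator df fixed at 3).
* White/Wooldridge: squared residuals regressed on fitted values and
  their squares; LM = n·R² ~ χ²(2). Note that genuine unmodeled
  moderation of the `b` path (as the default generator plants) makes
  E[u²] quadratic in the mediator, so a sensitive White test on the
  moderator-free summary model *should* occasionally flag it; at the
  default moderation strength this occurs in roughly one run in eight.
* Latent score: first principal component of column-standardized
  subtests, sign-aligned with the subtest sum (PCA sign is otherwise
  arbitrary), affine-rescaled to a target mean/SD.
* Framewise displacement: FD_t = Σ|Δtranslation| + r·Σ|Δrotation| per
  frame transition, rotation radius r = 50 mm by convention (exposed as
  a parameter), summarized as the mean and the proportion above 0.9 mm.
* Motion residualization replaces age, outcome, moderators, and every
  voxel (over its available subjects) by OLS residuals on the motion
  summaries; the operation is idempotent to 1e-10.

Both diagnostic tests are calibration-checked by simulation: empirical
type-I error within 0.05 ± 2 MC SEs over 2000 null replicates at n = 250.

## The synthetic study

The generator is the package's data source and defines its study
conditions:

* **Cohort**: n = 252, ages uniform on 20.5–90.3 y (a lifespan cohort
  with roughly equal numbers per decile; a uniform draw is simpler than
  any empirical histogram and sufficient for linear-model recovery).
  Moderators are standardized normals; motion summaries (mean FD in mm,
  high-motion proportion) drift mildly upward with age.
* **Voxel grid**: 16×16×10 at 3 mm isotropic by default — large enough
  for spatial statistics and missingness structure, small enough that
  the full pipeline runs in seconds. The central 40% block is the
  "activated" region; its demand response (intercept) and age slope are
  tapered radially (×1.5 at the centre to ×0.5 at the edge, unit mean),
  so response strength and mediation strength are genuinely coupled
  across voxels — the phenomenon the MSR correlation stage measures.
  Background voxels respond at zero mean.
* **Mediator model**: per-voxel value = intercept + a_v·age + shared
  regional error (Laplace, SD 0.4) + spatially smoothed voxel noise.
  White noise is smoothed with a Gaussian kernel (FWHM 8 mm) and
  renormalized by the discrete kernel's ℓ₂ norm so the configured SD
  (1.0) is the marginal SD away from grid edges (edge voxels under
  reflective boundaries deviate slightly). The shared regional error is
  what makes the *summary* mediator's structural error non-Gaussian —
  averaging many independent smoothed-noise voxels would otherwise
  produce a nearly Gaussian residual and silently break LiNGAM
  identifiability.
* **Outcome model**: intercept + c′·age + mean over active voxels of
  b_v·B_v + moderator terms + Laplace error (SD 15). Defaults: age slope
  −0.016 units/y (tapered), b = 9.375 points per unit, hence indirect
  effect −0.15 points/y of a −0.72 points/y total (≈ 21% mediated),
  marginal age–outcome r ≈ −0.66 and ≈ 7.2 points lost per decade. The
  "physical" moderator attenuates the b path by 4 points per SD; the
  "nonphysical" moderator is null. These values were chosen once so that
  every stage operates in its informative regime — voxel recall well
  above chance, direction recovery in the 85–95% range across replicate
  studies, moderation power ≈ 0.75 — and are the conditions the
  acceptance script reports under.
* **Missingness**: each subject, with probability 0.5, loses a
  contiguous slab from one random face of the volume with geometric
  depth (capped at a third of the axis), mimicking acquisition
  bounding-box truncation; a hard floor (default 100 subjects per
  voxel) is then enforced by restoring randomly chosen masked entries,
  so the floor invariant holds exactly.
* **Error families**: gaussian, laplace (default), uniform, and a
  skewed exponential mixture are available for the structural errors.
  The gaussian setting exists precisely to demonstrate
  non-identifiability of causal direction.
* **Confounder injection** builds `U` against the existing mediator
  summary and outcome with exact sample correlations (optionally in
  age-partialled space), returning `U` for oracle checks; it raises on
  target pairs incompatible with the observed mediator–outcome
  correlation.

What the generator does **not** emulate: haemodynamics or task design,
realistic brain geometry or tissue contrast, spatially varying noise,
site or session effects, and measurement error in age or the outcome.
Passing tests therefore demonstrate the statistical machinery's
correctness and calibration under the stated generating process, not
robustness to everything real data can do.

## Problem sizes and numerical choices

Simulation-based checks run at deliberately chosen desk scales: 2000
replicates for calibration of scalar tests, 50 replicates on a 20×20×10
grid for the voxel-wise hierarchy, 500 replicates × 999 permutations for
MSR calibration, 500 replicates × 2000 resamples for bootstrap coverage,
and scaled-down bootstraps (hundreds to thousands of resamples rather
than 15,000) wherever a Monte Carlo outer loop multiplies the cost; the
defaults on the public functions remain the full-scale values.
Tie-breaks and degenerate inputs are handled explicitly: rank-deficient
designs raise errors naming the offending regressor, constant maps and
empty masks raise rather than returning NaN, p-values from permutation
tests use the add-one convention, and quantiles use numpy's default
linear interpolation throughout (including inside the BC interval, so
enumeration oracles and sampled intervals agree).
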