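# Methods

This note documents the models and procedures implemented in `bigflica`,
the choices made where the design was genuinely open, and what the test
suite does and does not establish.

## The linked-ICA model

Given K modality matrices Y⁽ᵏ⁾ (N subjects × P_k features, z-scored per
feature), the model is a joint L-dimensional decomposition

    Y⁽ᵏ⁾ = H W⁽ᵏ⁾ X⁽ᵏ⁾ + E⁽ᵏ⁾,   k = 1…K,

with a single subject mode H (N × L) shared by all modalities, a positive
diagonal weight matrix W⁽ᵏ⁾ (one weight per component per modality),
modality-specific spatial sources X⁽ᵏ⁾ (L × P_k), and Gaussian noise E⁽ᵏ⁾
with a modality-specific precision τ_k.  The shared H is what links the
modalities: a component is one column of H together with its K spatial
maps, and W⁽ᵏ⁾ says how strongly each modality expresses it.

### Variational inference

The factorization is fitted by mean-field variational Bayes on the
reparametrization S⁽ᵏ⁾ = W⁽ᵏ⁾X⁽ᵏ⁾ (scales are separated again after
convergence; see below).  The variational family and priors:

* **H** — rows are independent Gaussians with a shared posterior
  covariance; standard-normal prior.
* **S⁽ᵏ⁾ elements** — each element has a 3-class zero-mean Gaussian-mixture
  posterior/prior.  Class precisions are α_{kl}·γ_c with fixed relative
  precisions γ = (100, 1, 0.01): a narrow "off" class, a middle class and a
  broad class.  The mixture makes the marginal source prior heavy-tailed —
  the spatial non-Gaussianity that ICA needs for identifiability.
* **α_{kl}** — a Gamma-distributed precision per modality and component
  (automatic relevance determination): a component unsupported by a
  modality has its source row shrunk toward zero there, and a globally
  unsupported component goes empty.  Empty components are reported, never
  silently removed.
* **Mixture weights** — Dirichlet per modality and component.
* **τ_k** — Gamma; this is where different overall modality
  signal-to-noise levels are absorbed.

Every update is the exact coordinate-ascent optimum of its factor, so the
variational free energy is non-decreasing; the fit monitors it each
iteration and raises a diagnostic error on any decrease beyond 1e-6
relative tolerance.  Two numerical points matter in practice:

* The mixture class log-weights contain a term b²/2ρ_c that can reach 1e9
  when the noise precision is large; the *differences* across classes are
  then far below float resolution of the raw terms.  They are therefore
  computed analytically relative to a reference class (the ρ_c differ only
  by α(γ_c − γ_ref), which cancels the huge common part exactly).  Without
  this the responsibilities turn into round-off noise and the free energy
  oscillates.
* The expected residual energy is floored at 1e-10 of the data energy so
  that exactly noiseless inputs cannot push τ to infinity.

**Update order** per iteration: sources → subject mode → ARD/mixture
weights → noise precisions.  **Initialization**: H from the top-L left
singular vectors of the column-concatenated inputs (via the N×N Gram
matrix), scaled to unit-RMS columns, plus 1% seeded Gaussian perturbation.
**Convergence**: relative free-energy change below `tol` (default 1e-6) or
`n_iter` (default 1000).  Fits are deterministic given the seed.

### Scale and sign conventions

The likelihood is invariant to rescaling (H, S); after convergence the
columns of H* are fixed to unit RMS, spatial maps to unit-RMS rows, and all
scale is carried by W⁽ᵏ⁾ ≥ 0 (component-k RMS × subject-mode RMS), so W is
comparable across modalities and components.  Each component is oriented so
that its pooled spatial skewness across modalities is positive.

### A known limitation: the near-noiseless regime

At extremely high SNR the posterior over (H, S) becomes so concentrated
that coordinate ascent cannot rotate the factorization away from its
(PCA-based) initialization — noise is what permits exploration.  Recovery
at the simulator's SNR grid (4 … 0.04) is unaffected; exactly noiseless
inputs recover the subspace but not necessarily the rotation.  The spatial
map reconstruction contract is therefore tested by closed-form regression
against a known subject mode, and ICA recovery on noisy simulations.

## Subject-space reduction (MIGP / mMIGP)

MIGP approximates the top-L* left singular pairs of an N × P matrix by
streaming column chunks through repeated small SVDs, keeping an m-column
sketch whose Gram matrix matches the columns seen so far.  When m is at
least the data rank the stream is *exactly* lossless (verified against a
direct SVD oracle at principal angles < 1e-8); with noise it is the usual
incremental-PCA approximation.  Defaults: sketch rank m = min(N, 2 L*)
("keep more than you need"), chunk = 10 m columns, deterministic column
order, sign fixed by making each column's largest-magnitude entry positive.

The multimodal extension runs MIGP per modality, concatenates the
unit-norm per-modality bases U˜⁽ᵏ⁾ column-wise (unweighted — relative
modality SNR is deliberately left to the linked-ICA noise model), reduces
the concatenation once more, and projects every modality onto the shared
basis: V⁽ᵏ⁾ = UᵀY⁽ᵏ⁾.  A reduced-space subject mode is returned to subject
space by H = U H*.  `explained_variance` reports the captured fraction of
the dataset's total sum of squares, ‖UᵀY‖²/‖Y‖² summed over modalities,
which is 1 at L* = N and monotone in L* — the quantity used to choose L*.

## Feature-space reduction (sparse dictionary learning)

Voxels are correlated locally and across networks, so the feature dimension
is reduced by coding data *columns* (voxels) sparsely over a
norm-constrained subject-space basis:

    minimize over A, D:  Σᵢ ‖Vᵢ − A Dᵢ‖² + λ‖Dᵢ‖₁    s.t. ‖A_j‖₂ ≤ 1,

where A (rows × L**) is dense and D (L** × P) is sparse; the linked ICA
consumes the feature loadings A, not the dictionary D.  Spatial maps are
recovered afterwards by voxel-wise regression of the data on the subject
mode.  Overcomplete dictionaries (L** larger than either dimension) are
allowed.

Optimization is batch block-coordinate descent: a coordinate-descent lasso
in D (all voxels share the design matrix A, so the scalar updates vectorize
across voxels; the kernel is JIT-compiled when numba is present, with an
identical pure-numpy fallback) alternated with per-atom least-squares
updates of A projected onto the unit ball.  Both half-steps are exact
block minimizers, so the per-epoch objective trace is monotone
non-increasing — asserted in the tests together with an exact brute-force
re-evaluation of the objective and the Eckart–Young lower bound on the
reconstruction error.  Atoms left unused at the end of an epoch are
re-seeded from the worst-reconstructed voxel with a still-zero code row,
which leaves the objective unchanged.  Defaults: λ = 1, 50 epochs,
initialization from randomly chosen norm-clipped data columns (seeded).
λ is not rescaled with problem size.

## Pipeline order

When both reductions are enabled the order is mMIGP first, then DicL on
the projected data (L* × P_k), then the linked ICA on the K loadings
matrices (L* × L**); dimension feasibility L < min(L*, L**, N) is checked
before any computation.  Running DicL directly on raw data (N × P_k) is
also supported for single-stage use.

## The simulator

Each simulated dataset follows the generative model above with known
ground truth, on a 3D grid: source maps are 0.05 × full-grid white noise
plus 0.95 × white noise on a randomly placed 5×5×5 cube, then smoothed
with a Gaussian kernel of σ = 1 voxel (a light smoothing chosen to mimic
the spatial autocorrelation of real maps; the kernel width is this
package's choice).  Component weights are Uniform(0.5, 1.5); subject
loadings and noise are Gaussian, with the noise also smoothed.  Defaults
define the reference conditions: 500 subjects, two modalities, 30×30×30
grids (27,000 voxels), 25 shared components plus 5 unique components per
modality (realized as extra rows of X whose weight is zero in the other
modality).  The noise scale σ is solved analytically so that the realized

    SNR = var(vec(HWX)) / var(vec(σE))

matches the configured value, and is verified empirically.  Voxels are
z-scored before the data are handed to the pipeline.  Identical
configuration and seed give bit-identical datasets.

What the simulator does not emulate: MRI artifacts, registration error,
spatially varying noise, inter-subject anatomical variability, realistic
modality-specific spatial covariance.  Passing recovery tests establish
correctness of the algorithms under the stated generative model, not
performance on real scanner data.

## Evaluation protocols

* **Component matching** — greedy maximum-|correlation| pairing of
  estimated against ground-truth subject-loading columns; all-zero
  estimated components are excluded; ties break toward the lower estimated
  index; the score is the mean |r| over matched pairs.
* **Phenotype prediction** — per phenotype: drop missing subjects, outer
  5-fold split (seeded, reused verbatim when two feature sets are
  compared), optional univariate screening of the top-k |r| features
  computed on the training fold only, elastic-net tuning by inner 5-fold
  CV over mixing ∈ {0.01, 0.1, 0.5, 0.9, 1.0} × a 50-point penalty path,
  accuracy = Pearson r between pooled test-fold predictions and truth.
  Phenotypes are never imputed; confounds are regressed out of phenotypes
  beforehand by per-column OLS with an intercept on the observed rows.
* **GLS weighted paired test** — comparing two methods' per-phenotype
  accuracies must respect the correlation among phenotypes; a naive paired
  t-test is anticonservative there.  After excluding phenotypes where both
  methods score r < 0.1, the difference vector is tested with
  β = (xᵀV⁻¹x)⁻¹xᵀV⁻¹y (x a column of ones), the stated
  (p₁−1)-denominator variance estimate, t = β/√s with p₁−1 degrees of
  freedom, and V the sample covariance of the retained phenotypes
  (shrunk toward its diagonal only when ill-conditioned).  With V = I this
  reduces exactly to the classic paired t-test.  The reported z is the
  signed inverse-normal transform of the two-sided p.  Calibration note:
  V is a plug-in estimate, so its own sampling noise inflates the test
  slightly when the subject count is only a few times p₁ (empirical size
  ≈ 0.15 at 500 subjects for 200 phenotypes, ≈ 0.065 at 2000); the type-I
  simulation therefore uses 8000 subjects for 200 phenotypes — the
  biobank-scale regime the test is meant for — where the empirical size is
  nominal (≈ 0.055).
* **Split-half reproducibility** — seeded random half-split of subjects,
  the full pipeline run per half, z-scored spatial maps concatenated
  across modalities per component, greedy pairing by |correlation|
  computed only over voxels with |z| > 3 in *both* runs; pairs with fewer
  than 10 surviving voxels are flagged and excluded from the median.
* **Prediction stability** — per-phenotype accuracies over several seeded
  train-test splits, reported as deviations from the per-phenotype mean.
* **Modality contributions** — the diagonals of W⁽ᵏ⁾ stacked into a
  mode × modality matrix with columns normalized to sum to one; modality
  relationships are cosine similarities between columns.  Both marginal
  sums of the normalized matrix are computable; note that the column-sum
  marginal is identically 1 by construction, so the informative summaries
  are the per-mode profile and the column cosine similarities.

## Problem sizes used in the tests

The reference simulation conditions (N = 500, K = 25 shared + 5 unique per
modality, SNR ∈ {4, 0.04}) are kept, with the grid at 15×15×15 (3,375
voxels) and the dictionary size scaled with the voxel count
(250 = 2000 × 3375/27000); recovery experiments use 10 seeds, the GLS
type-I simulation 1000 replicates, and the prediction-null check 20
replicates.  Linked-ICA fits in the recovery experiments run to free-energy
convergence at tol 1e-6 (typically 300–600 iterations at these sizes) —
convergence matters: stopping such fits early measurably lowers recovery.

## Known limitations

* The VB core stores dense posterior statistics (≈ 5 float arrays of size
  3·L·P per modality); very large raw inputs should pass through the
  reductions first, which is the intended usage.
* Rotation recovery degrades in the exactly-noiseless regime (above).
* The GLS test's plug-in covariance slightly inflates its size when the
  subject count is not large relative to the retained phenotype count.
* The elastic-net harness models linear phenotype-feature relationships
  only.
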