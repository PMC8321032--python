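# Methods

## The multilevel model

The analysis operates on n subjects × p coordinates, p = 3K for K named
landmarks flattened landmark-major (x₁, y₁, z₁, x₂, …), so one landmark's
(x, y, z) always occupies a consecutive triple. Coordinates are assumed to
be Procrustes-superimposed before modelling (`gpa_align` provides this).

A shape is modelled as the grand mean plus additive contributions from four
non-nested levels — maternal smoking, maternal alcohol, biological sex, and
subject — each with its own covariance matrix and eigenmodes. The design is
non-nested: any sex can occur in any smoking or alcohol group, so each
level's covariance is built independently rather than by sequential
conditioning.

### Level covariances

**Factor levels.** For a factor with G groups we form each group's
*marginal* mean (pooling over the other factors), centre the G means by
their **unweighted** average, and divide by **G**:

    C_factor = (1/G) Σ_g (m_g − m̄)(m_g − m̄)ᵀ .

Two deliberate conventions: marginal pooling is the natural reading of a
non-nested design, and the unweighted mean with divisor G keeps the level
insensitive to group-size imbalance, which is severe here (cells range from
15 to 775 subjects). The rank of C_factor is at most G − 1; retention
requests beyond that bound are refused with an error citing the rule, and
the sex level (G = 2) can therefore carry exactly one mode.

**Subject level.** Residual structure is measured within the full
smoking × alcohol × sex cross (18 cells). Each cell c with n_c ≥ 2
contributes its within-cell covariance (divisor n_c, deviations about the
cell mean); cells below two subjects are skipped and reported. The level
covariance is the **element-wise median** over cells. The median makes the
estimate robust: replacing one non-median cell's covariance by an
arbitrarily inflated matrix leaves the result unchanged. The element-wise
median of PSD matrices need not stay PSD, so the eigendecomposition clamps
negative eigenvalues to zero and records the removed mass.

### Eigendecomposition and retention

Each level covariance is symmetrised and decomposed with `scipy.linalg.eigh`;
eigenvalues are sorted descending, values below 10⁻¹² × trace (or negative)
are clamped to zero, and each eigenvector's sign is fixed so its
largest-magnitude coordinate is positive (signs are otherwise arbitrary and
implementations are expected to differ). Retention counts are a
configuration input — the default (2, 2, 1, 35) mirrors a scree-plot choice
for this design and is capped at each level's available rank; no automatic
scree criterion is applied. Eigenvalue ties are left in the decomposition's
stable order; the subspace, not the individual vectors, is then the
meaningful object.

### Variance partition

A level's percentage of total variation divides its (retained) eigenvalue
mass by the **sum of all eigenvalues over all levels, retained or not**.
With this denominator the per-level retained percentages need not sum to
100; the shortfall is exactly the unretained eigenvalue mass.

### Simultaneous score fitting

A configuration's scores on all levels are fitted at once by minimising the
point-to-point cost ‖z − μ − B a‖², with B the horizontal concatenation of
every level's retained modes. The cost is quadratic, so the global optimum
is the linear least-squares solution; we use the pseudoinverse, which gives
the minimum-norm solution when B is column-rank-deficient (modes across
levels need not be independent — with few landmarks the level subspaces can
overlap heavily). The pseudoinverse is applied row by row so batch and
single-observation fits agree bitwise. A generic iterative optimiser
(`fit_iterative`) is retained solely as an equivalence check; on
ill-conditioned B it converges more slowly to the same optimum.

Standardized scores divide by √λ of the respective mode (0 where λ = 0, by
convention). Group centroid tables report the sample SD (divisor n − 1);
singleton groups report SD 0 and are flagged. Landmark-difference tables
reconstruct the mean face at ±2√λ along one mode and tabulate the
difference, which equals 4√λ·u reshaped to K × 3 exactly.

### Conventional PCA baseline

`conventional_pca` eigendecomposes the overall covariance about the grand
mean using the **population divisor n**, matching the divisor conventions of
the level construction. This makes the degeneracy exact: a model whose only
level treats every subject as its own group reproduces conventional PCA's
eigenvalues to machine precision, which the tests exploit as an oracle.

## Procrustes superimposition

Full generalized Procrustes: every configuration is centred and scaled to
unit centroid size, rotated to the current consensus by orthogonal
Procrustes restricted to proper rotations (faces have handedness; no
reflections), and the consensus re-estimated until the change in total
squared Procrustes distance falls below `tol` (default 1e-8, `max_iter`
100). Non-convergence raises a warning but still returns the result; a
configuration with zero centroid size is an error naming the subject.
Scaling is included because the analysis targets shape, not size. No
tangent-space projection is applied; aligned coordinates feed the model
directly. `procrustes_distance` computes the full Procrustes residual
directly from the optimally rotated and scaled pair, which stays accurate
(≈10⁻¹⁵) for nearly identical shapes where the closed form √(1 − s²) loses
precision.

## Monte Carlo eigenvalue errors

A single pooled Gaussian (μ = grand mean, Σ = sample covariance, divisor
n − 1) is fitted to the aligned data; each of the (default 1000) replicates
redraws all n rows from it, inherits the original subjects' factor labels
row-for-row — keeping every group and cell size fixed, which the level
covariances require — rebuilds the full model, and records the retained
eigenvalues. The SD across replicates estimates each eigenvalue's standard
error. Pooling ignores group mean differences by construction, so these are
broad calibration estimates, not exact sampling distributions. Replicate r
draws from its own generator spawned from `SeedSequence(seed)`, so raising
the replicate count extends, never reshuffles, the earlier replicates, and
a fixed seed reproduces results bit for bit. Σ may be singular; sampling
uses a symmetric eigenfactor with negative eigenvalues (beyond tolerance)
rejected.

## Synthetic cohorts

`simulate` draws subject i in cell (g₁, g₂, g₃) as

    zᵢ = template + δ_smoking(g₁) + δ_alcohol(g₂) + δ_sex(g₃) + εᵢ ,

with εᵢ ~ N(0, Σ_subject). Defaults emulate the study conditions:

* **Template** — a symmetric 21-point face in mm, centred at the origin.
* **Cell sizes** — the study's 18 smoking × alcohol × sex cells
  (574, 622, …, 121; n = 3755), preserving its strong imbalance.
* **Effect vectors** — per factor, per group, spatially smooth offsets
  (drawn from a squared-exponential kernel over inter-landmark distance)
  centred to zero under unweighted group averaging and scaled so the
  factor's between-group mass (1/G) Σ‖δ_g‖² hits a requested fraction of
  total variation. The `paper_like` preset plants sex ≈ 8.9%,
  smoking ≈ 0.7%, alcohol ≈ 0.5% — the regime the motivating study reports.
* **Subject noise** — squared-exponential spatial covariance (amplitude
  3 mm, range 30 mm, plus 1 mm iid jitter), i.e. neighbouring landmarks
  move together, as facial soft tissue does.
* **Shape space restriction** — effects and noise are projected onto the
  orthogonal complement of the similarity-transform tangent space at the
  template (translations, rotations, scaling; 7 dimensions). Procrustes
  superimposition removes exactly these directions to first order, so the
  generator plants structure where the analysis can see it and the analytic
  decomposition survives alignment. Without the projection, alignment
  strips ≈11% of an unrestricted noise trace and the planted fractions
  would be systematically wrong.
* **Rigid jitter** (optional) — a random proper rotation, translation
  (±20 mm) and scale (×0.9–1.1) per subject, to exercise the
  superimposition.

`expected_variance_fractions` returns the closed-form decomposition **under
the pipeline's own conventions**: expected marginal group means are pooled
with the actual cell sizes, so the imbalance-induced leakage of one
factor's effect into another's marginal means is included exactly; the
subject mass is trace(Σ_subject) (all cells share Σ, so the median equals
it). Finite-sample noise inflation of the group-mean covariances (of order
trace(Σ)/n_g, ≈0.3 percentage points for the smallest factor groups at
n = 3755) is not added; it sits well inside the ±1.5 point recovery
tolerance the tests use.

What the generator does **not** emulate: landmarking measurement error and
rater effects, non-Gaussian or heteroscedastic subject variation,
exposure-dependent covariance changes, and any continuous dose structure.
Passing recovery tests therefore demonstrates correctness of the
machinery under the additive Gaussian design, not robustness to those
real-data features.

## Problem sizes and determinism

The test suite and the acceptance script run the full-size synthetic cohort
(n = 3755, p = 63) for recovery and invariance checks, a 90-subject
3-landmark preset for fast unit tests, and 1000-replicate Monte Carlo runs
at p = 1 for SE calibration; everything completes in seconds on one CPU.
All randomness is seeded; simulation, alignment, model building and Monte
Carlo are deterministic given the seed.

## Known limitations

* Missing landmarks are rejected outright; the method has no missing-data
  handling.
* No inferential testing between groups (bootstrap inference is a natural
  next step); the descriptive tables carry no p-values.
* Only the non-nested design is implemented — no nested or mixed levels,
  e.g. repeated scans per subject.
* The choice of retained components is manual (scree-style), and the
  variance-partition denominator convention means reported percentages
  depend on it only through the numerator.
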