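# Methods

## Objective and conventions

All methods are scored on raw stress between the input distance matrix
`D_X` and the embedding distance matrix `D_Y`,

    σ = Σ_{i,j} w_ij ((D_X)_ij − (D_Y)_ij)² ,

summed over **all ordered pairs** including the zero diagonal, so that with
unit weights σ = ‖D_X − D_Y‖_F². The halved (unordered-pair) convention
used by some software is exactly σ/2; we keep the Frobenius form because
the algebraic identities of the linear theory — `‖D_X‖_F² = 2n‖X‖_F²` for
row-centered `X`, and the rank-dependent bound below — are stated in it.
Default weights are 1; the Sammon preset `w_ij = 1/(D_X)_ij` (diagonal 0)
is exposed but never used by default. Input metrics: Euclidean, cosine
(1 − cosine similarity), correlation (1 − Pearson r of the two rows);
cosine rejects all-zero rows and correlation rejects constant rows
explicitly. Output-space distances are always Euclidean.

Dense `n × n` matrices (distances, SMACOF) are only materialized for
`n ≤ 20,000` (configurable); above that, `stress_estimate` reports a
sampled-pair Monte-Carlo estimate and is labeled as such.

## The neural embedding

The map is `y = tanh(x W₁ + b₁) W₂ + b₂`: one hidden tanh layer, linear
output (stress needs unbounded output coordinates, so no output
activation). A single-hidden-layer network with a sigmoidal activation is
a universal approximator on compacta, which is all the capacity this
problem needs; the parameter count is tiny relative to `n·m`, limiting
overfitting — the held-out stress ratio test confirms the map generalizes.

**Hidden width.** By default the intrinsic dimension of the data: the
smallest `h` whose top-`h` singular values of the row-centered matrix carry
≥ 95% of the squared-singular-value mass, raised to the output dimension
`k` if smaller (a bottleneck narrower than the output cannot help).
Centering before the SVD makes the ratio a variance ratio.

**Training.** Rows are shuffled each epoch and cut into batches of 256; per
batch the loss is the sum over its 32,640 unordered pairs of
`(d(x_i,x_j) − ‖y_i−y_j‖)²`, with batch distances computed on the fly —
no `n × n` matrix ever exists, which is what makes the method linear in
`n` per epoch. Gradients are exact (analytic backpropagation through the
pair loss) and applied with Adam (β₁ = 0.9, β₂ = 0.999). The loss is
summed, not averaged, over pairs; averaging is exposed as an option since
it only rescales the gradient under Adam.

**Learning rate 1e−2 (default).** At desk-scale problem sizes
(`n ≲ a few thousand`, batch 256) an epoch contains only a handful of Adam
steps, and Adam's effective parameter speed is bounded by roughly the
learning rate per step regardless of loss scale. At 1e−3 the optimizer
cannot traverse the needed parameter distance within realistic epoch
budgets and stalls above the stress of the linear baselines; at 1e−2 it
converges on every configuration we test (open box, Gaussian clusters,
two-point geometry) and is stable over thousands of epochs. The rate is a
config parameter for users with larger step budgets.

**Initialization and determinism.** Weights are symmetric scaled-uniform
(Glorot): `U(−a, a)` with `a = √(6/(fan_in+fan_out))`; biases zero. One
`numpy` Generator seeded by `random_state` drives initialization and all
epoch shuffles, so identical data + config + seed reproduce the embedding
bit-for-bit. A non-finite batch loss aborts with the offending epoch.
Trailing batches with fewer than two points are skipped (no pair exists).

**Out-of-sample mapping and persistence.** `transform` is a pure forward
pass through the stored weights, after replaying the stored feature
standardization if it was enabled at fit time. Models serialize to a
versioned JSON container (dims, weights, preprocessing state, config);
loading a newer major version fails loudly, and a round-trip reproduces
`transform` bit-for-bit.

## SMACOF

Unweighted Guttman-transform majorization on a precomputed distance
matrix: `Y ← (1/n) B(Y) Y` with `b_ij = −d_ij/‖y_i−y_j‖` (0/0 terms from
coincident points defined as 0) and `b_ii = −Σ_{j≠i} b_ij`. Each transform
minimizes a quadratic majorizer touching the stress at the current
configuration, so the recorded stress trace is non-increasing — a property
the tests assert on every instance. Default initialization is the
classical-MDS configuration (top-k eigenpairs of the double-centered
squared distances), which both accelerates convergence and guarantees the
final stress is at most the classical-MDS stress; random initialization is
available. Convergence: relative stress change < 1e−6 or 300 iterations.
Dense and quadratic in `n`, hence refused above the 20,000-point cap.

## Classical MDS / PCA and random projection

On explicitly given points classical MDS equals PCA: row-center, project
onto the top-k right singular vectors. The returned loading matrix maps
unseen points linearly. The equivalence with the distance-matrix route
(eigendecomposition of `−½HD²H`, `H = I − ee^T/n`) is asserted in the
tests. Random projection uses an i.i.d. Gaussian matrix with entries
`N(0, 1/k)`, preserving squared distances in expectation
(Johnson–Lindenstrauss); the matrix is returned for mapping unseen points.

## Projected metric MDS

The intermediate problem `min_P ‖D_X − D_{XP}‖_F²` keeps metric-MDS's
objective but forces a linear map `Y = XP`. Two exact results are
implemented and tested:

* the least-squares projection onto the column space of `X`:
  `P̃ = V₁Σ̃⁻¹U₁ᵀỸ` from the thin SVD restricted to the `r` nonzero
  singular values, with residual `‖Ỹ − XP̃‖_F² = ‖U₂ᵀỸ‖_F²`. The numerical
  rank uses the tolerance `σ₁·max(n,m)·ε_machine` (overridable); the
  construction is the pseudo-inverse solution, so rank deficiency needs no
  error path;
* the approximation bound `‖D_Ỹ − D_{XP̃}‖_F ≤ √(n−r+2)·‖D_Ỹ‖_F` for
  row-centered `X` and any candidate configuration `Ỹ`. The bound is
  stated constructively for the `P̃` above — optima of either problem are
  not computable exactly, so the for-all-`Ỹ` form is what the
  `bound-check` diagnostic verifies.

The stress objective itself is minimized over `P` by L-BFGS with an
analytic gradient, each output distance smoothed as `√(‖·‖² + ε)`
(ε = 1e−6 by default) so the objective is differentiable at coincident
points; `√(·+ε)` is the standard smooth surrogate for the Euclidean norm.
Initialization is the PCA loading matrix, and L-BFGS's line search only
accepts decreases, so the final objective never exceeds PCA's stress.
Convergence: relative objective change < 1e−8 or 500 iterations.

## Synthetic data

The generators are pure functions of (parameters, seed) and define the
conditions every test runs under.

* **open_box(n, side=1, seed)** — uniform on the five faces of the
  lidless cube `[0, side]³` (top face removed). All five faces are squares
  of equal area, so faces are sampled uniformly; labels record the face.
  This is the canonical surface where nonlinear mMDS beats every linear
  map: the box must be *unfolded* to lie flat.
* **gaussian_clusters(n, m=20, c=4, separation=10, seed)** — balanced
  isotropic unit-variance blobs whose centers are rescaled to pairwise
  distance ≥ `separation`. The default of 10 within-cluster standard
  deviations is a cleanly separated regime comparable to distinct cell
  types after feature selection.
* **scrna_like_counts(n_cells=500, n_genes=2000, c=3, seed)** — sparse
  integer counts: log-normal baseline rates per gene, an 8-fold
  up-regulated random 5% marker set per cluster, log-normal per-cell
  library factors, Poisson sampling. At defaults ≥ 80% of entries are
  zero. This emulates the sparsity and block structure of droplet
  scRNA-seq, **not** its full noise model (no proper overdispersion fit,
  no batch effects, no ambient RNA); tests passing on it show the pipeline
  handles sparse count geometry, not that it reproduces any particular
  biology.

## Problem sizes in the checks

The end-to-end checks use n = 400–1000 points: large enough that the
minibatch pair sampling, the train/test protocol and the method ordering
(neural < PCA < random projection on the box; neural ≈ SMACOF on
clusters) are all exercised, small enough that every suite runs in about a
minute on one CPU. The scaling property is asserted as a wall-time ratio
(4× the points ⇒ ≤ 5× the time) rather than an absolute benchmark.

## Known limitations

* Stress is a nonconvex objective everywhere in this package; SMACOF and
  the neural optimizer find local minima, and the neural/SMACOF stress
  ratio on cluster data varies by generator seed (typically 1.0–1.1,
  occasionally worse when one method lands in a poorer basin).
* The neural map's quality at very small epoch budgets depends on the
  learning rate (see above); no automatic schedule is provided.
* Cosine/correlation metrics apply to the input space only; the embedding
  space is always Euclidean.
* No GPU path; everything is numpy/BLAS.
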