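# Methods

## Model

Given V views X_v ∈ R^{p_v×n} describing the same n samples in the same
order, each view is modelled as lying near a d-dimensional subspace of its
feature space, d = d0 + d_v < p_v, spanned by an orthonormal basis
P_v = (P_v^(c)  P_v^(s)):

    X_v = P_v^(c) C + P_v^(s) S_v + E_v.

C ∈ R^{d0×n} is a sample representation shared by all views; S_v ∈ R^{d_v×n}
is specific to view v.  Because P_v is orthonormal, the common and specific
subspaces of a view are orthogonal, so each view's representation is a clean
concatenation [C; S_v].  The model is estimated by minimizing

    f(P, C, S) = Σ_v ‖X_v − P_v [C; S_v]‖_F² + β Σ_v tr(CᵀC H S_vᵀS_v H),

where H = I − eeᵀ/n and the second term is the empirical linear-kernel HSIC
between C and S_v (the proportionality constant of the population estimator
is dropped).  The penalty pushes the common and specific representations
toward statistical independence; the model's key assumption is that the
shared structure, however weak in energy, is present in *every* view, while
specific structure is not reproducible across views.

Nonlinear kernels inside the optimization, missing data and sparse inputs
are out of scope.

## Optimization

Three exact block updates alternate, in the order S → P → C:

1. **Specific parts.**  With P_v and C fixed, the stationarity condition is
   the Sylvester equation
   (P_v^(s))ᵀP_v^(s) S_v + β S_v H CᵀC H = (P_v^(s))ᵀX_v − (P_v^(s))ᵀP_v^(c) C.
   Since P_v^(s) has orthonormal columns the left coefficient is the
   identity, and the equation reduces to one symmetric positive-definite
   solve S_v (I + β H CᵀC H) = RHS.  The implementation uses this reduction
   (computing H CᵀC H as the Gram matrix of the column-centered C, never
   forming H); a general Bartels–Stewart path (`method='sylvester'`) is kept
   for cross-checking and the two agree to solver precision.
2. **Bases.**  With Z_v = [C; S_v] fixed, minimizing ‖X_v − P_v Z_v‖_F²
   over orthonormal P_v is the orthogonal Procrustes problem, solved in
   closed form by the thin SVD X_v Z_vᵀ = UΣVᵀ, P_v = UVᵀ.  This is the
   exact minimizer of the quadratic subproblem, equivalent to iterative
   Grassmann-manifold descent for this objective.  When X_v Z_vᵀ is
   rank-deficient the minimizer is non-unique; the SVD factors provide a
   deterministic orthonormal completion and a warning is emitted.
3. **Common part.**  The pooled stationarity condition
   (Σ_v (P_v^(c))ᵀP_v^(c)) C + β C (Σ_v H S_vᵀS_v H) = Σ_v [(P_v^(c))ᵀX_v −
   (P_v^(c))ᵀP_v^(s) S_v] has left coefficient V·I by orthonormality and is
   again one symmetric solve.

Each step minimizes f exactly over its block, so the objective trace
recorded after every outer cycle is non-increasing and bounded below by 0.
Iteration stops when |f_k − f_{k−1}| / max(1, f_{k−1}) < tol
(default 1e-6) or after `max_iter` (default 100) cycles.  Penalty-dominated
regimes (large β at strong specific signal) can flatten slowly and may not
reach the stopping tolerance within the cap; the trace remains monotone.

**Initialization and restarts.**  Run 1 starts from the top d0+d_v left
singular vectors of each X_v, with C initialized as the view-average of the
first d0 rows of P_vᵀX_v and S_v as the remaining rows; further runs start
from seeded random orthonormal bases (QR of Gaussian).  The alternating
scheme has genuinely bad local minima in which the common and specific roles
are swapped — the view-averaged warm start can cancel across views when the
per-view SVD bases disagree in sign — so `fit_isc` performs `n_init` = 3
restarts and keeps the run with the lowest final objective.  Everything is
deterministic given the seed.

## Model selection

- **Representation choice.**  With no ground truth, the silhouette score of
  the k-means clustering is compared across the common and specific
  representations (`select_best`); ties prefer the common part, then the
  lowest view index.
- **HSIC weight.**  β is selected from the grid {0} ∪ {10⁻⁶, …, 10⁶}
  (`select_beta`).  The criterion is the silhouette of the best
  representation, restricted to *reconstruction-admissible* fits: grid
  entries whose reconstruction error exceeds `recon_tol` (default 10) times
  the grid-wide minimum are excluded before silhouettes are compared.  The
  rationale: the HSIC term regularizes the decomposition but does not
  replace it — past a data-dependent threshold the penalty dominates, the
  fit stops describing the data (reconstruction error inflates by orders of
  magnitude), and silhouettes of such representations are not comparable
  with those of genuine decompositions.  Without the admissibility filter
  the grid search can prefer a degenerate common part with a high silhouette
  but no relation to the shared structure.
- **k-means protocol.**  Each representation is clustered `runs` = 100 times
  (Lloyd with k-means++ seeding, one restart per run; run seeds derived
  deterministically from one master seed).  Evaluation metrics and the
  silhouette are arithmetic means over runs; the representative labeling is
  the minimum-inertia run.  A zero-variance representation yields a single
  cluster with silhouette 0, keeping selection total.  The number of
  clusters k is a user input, not estimated.

## Evaluation metrics

NMI uses 2·MI/(H₁+H₂) with log base 2; when both partitions have zero
entropy the value is 1, when exactly one has zero entropy it is 0 (the
formula is 0/0 there).  ACC matches predicted to reference clusters by the
Hungarian algorithm on the contingency table before counting agreement, so
it is invariant to relabeling.  ARI uses the pair-counting form
(RI − E[RI])/(max RI − E[RI]) with the degenerate max RI = E[RI] case
defined as 1 for identical partitions and 0 otherwise.  The silhouette is
the mean of (b−a)/max(a,b) with Euclidean distances; samples in singleton
clusters score 0.  All four are implemented from their definitions and
cross-checked against independent implementations in the test suite.

The consensus score of view v,
C-score_v = tr(H X_vᵀX_v H CᵀC) / tr(H X_vᵀX_v H (CᵀC + S_vᵀS_v)), is
computed with X_v exactly as passed (no internal standardization; a
`--standardize` flag exists in the CLI, off by default).  Both traces are
congruences of PSD matrices, so the score lies in [0, 1].  When both C and
S_v are constant across samples the ratio is undefined and a ValueError is
raised.

## Synthetic benchmark

The generator emulates a two-view scenario with tunable cross-view
inconsistency.  Y (2×n, default n = 200) holds exactly n/2 samples from
each of N([−4, 6], diag(10, 6)) and N([3, −10], diag(10, 6)).  Per view:
Y_v = Y + white noise; T_v = Y_v with its columns permuted uniformly at
random (an independent permutation per view); X_v = P_v [Y_v; t·T_v] with
P_v an 8×4 random matrix, orthonormalized by QR by default (a raw-Gaussian
mode is available).  Ground truth: y for the common part, y∘perm_v for each
specific part; the specific parts of different views agree with each other
only by chance, so large t makes the views inconsistent.  The ladder
t ∈ {0.1, 0.9, 1, 2, 5, 6, 10, 15, 20, 30} spans consensus scores from ~1
down to ~1e-6.

**Noise level.**  The additive noise sd defaults to 0.1.  This is forced by
an energy-accounting argument: at t = 0.1 the scaled specific signal t·T_v
carries energy t²‖Y H‖² ≈ 184, while noise at sd 1.0 would carry
2·n·sd² = 400 per view — the fitted specific part would then capture the
noise rather than t·T_v and the view consensus score would collapse to
~0.02 instead of ~0.9998.  At sd 0.1 the noise energy (4) is well below the
weakest specific signal on the ladder, the views still differ (Y_1 ≠ Y_2),
and the t = 0.1 consensus score reproduces to four decimals.

**What the generator does not emulate:** unequal feature counts or noise
levels across views, non-Gaussian marginals, unbalanced or more than two
clusters, and features on heterogeneous scales — so passing benchmark tests
demonstrates correct recovery of a planted linear common/specific structure,
not robustness to real multi-omics artifacts.

## Numerical choices and edge cases

- Linear solves use symmetric positive-definite factorizations; β < 0 is
  rejected at construction, so the systems are always well posed.
- Orthonormality of every fitted basis holds to ~1e-15 (Procrustes output).
- Mixture draws place a boundary sample on the wrong side of the optimal
  separating plane in a minority of datasets (~3σ tail events at n = 200);
  k-means then consistently assigns it to the nearer cluster, giving
  accuracy 0.995 rather than 1.0 for those seeds.  Metrics are therefore
  averaged over generator seeds in benchmark checks.
- Ties in silhouette-based selection are broken toward the common part,
  then the lowest view index; ties in the β grid keep the earliest entry.

## Known limitations

- d0 and d_v are user inputs; the package provides no estimator for them.
  The benchmark uses d0 = d_v = 2, matching its 8×4 construction.
- The alternating scheme guarantees monotone convergence to a stationary
  point, not a global optimum; restarts mitigate but cannot exclude local
  minima.
- The ISC-C silhouette measured on the benchmark (~0.71–0.83 across the
  ladder) is what a faithful 2-D two-Gaussian common part yields with these
  mixture parameters (within-cluster mean pair distance ≈ 5 against a
  between-center distance ≈ 17.5); substantially higher values would
  require a common representation that compresses within-cluster variance,
  which the reconstruction term resists.
- Runtime is dominated by the n×n solves; fits are practical to n of a few
  thousand but the implementation is dense throughout.
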