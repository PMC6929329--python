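# iscluster

Integrative subspace clustering of multi-view data by common/specific
decomposition, with a reproducible two-view simulation benchmark.

## The problem

Multi-omics studies describe the same n samples through several feature
matrices ("views") — e.g. mRNA expression, DNA methylation and miRNA
expression for one patient cohort.  Most integrative clustering methods
assume the views agree strongly about the clustering structure; when the
shared signal is weak relative to view-specific structure they fail, and
none of them tells you *which* view carries conflicting structure.  Yet in
cancer subtype identification the view-specific structure may itself be the
biology of interest.

`iscluster` decomposes each view X_v ∈ R^{p_v×n} into a sample
representation shared by all views and one specific to that view, living in
orthogonal subspaces of the view's feature space:

    X_v = P_v [C; S_v] + E_v,        P_vᵀ P_v = I,

where C (d0×n) is the common representation, S_v (d_v×n) the view-specific
one, and P_v an orthonormal basis whose first d0 columns span the common
subspace.  The fit minimizes

    Σ_v ‖X_v − P_v [C; S_v]‖_F²  +  β Σ_v tr(CᵀC H S_vᵀS_v H),

reconstruction error plus a linear-kernel HSIC (Hilbert–Schmidt Independence
Criterion) penalty that discourages statistical dependence between the
common and specific representations (H = I − eeᵀ/n is the sample centering
matrix).  The optimizer alternates three exact block updates — a Sylvester
solve for each S_v, an orthogonal-Procrustes SVD for each P_v, and a pooled
Sylvester solve for C — so the objective is non-increasing by construction.
k-means on the columns of C gives the consensus clustering; k-means on each
S_v exposes each view's private structure.  A per-view consensus score

    C-score_v = tr(H X_vᵀX_v H CᵀC) / tr(H X_vᵀX_v H (CᵀC + S_vᵀS_v)) ∈ [0, 1]

quantifies how much of the view's centered similarity structure the common
part explains.

## Worked example

```python
import numpy as np
from iscluster import ISCModel, simulate_two_view

# two-view benchmark: shared 2-D Gaussian mixture plus a column-permuted,
# t-scaled specific copy per view, mixed into 8 features
bundle = simulate_two_view(t=10.0, seed=1)

model = ISCModel(bundle.X, d0=2, d_spec=2)
res = model.fit_select_beta(k=2, runs=100, seed=1)   # beta from the grid
print(res.summary())
```

```
Integrative Subspace Clustering Results
=======================================================
Views                       2
Samples (n)                 200
Features per view           (8, 8)
Common dim (d0)             2
Specific dims               (2, 2)
HSIC weight (beta)          1e-06
Iterations                  28
Converged                   True
Objective                   105.124
-------------------------------------------------------
View       rel. recon. error       C-score
1                  3.332e-03     0.0001161
2                  3.378e-03     0.0001073
=======================================================
```

At t = 10 the view-specific signal is 10× stronger than the shared one, so
the consensus scores are tiny (~1e-4): almost all of each view's structure
is view-specific.  The decomposition still isolates the weak shared signal:

```python
out = res.cluster(k=2, runs=100, seed=1,
                  truth_common=bundle.y, truth_specific=bundle.y_spec)
for o in out:
    print(o.source, round(o.mean_metrics.acc, 3), round(o.silhouette, 3))
```

```
common 0.995 0.739
specific_1 0.995 0.738
specific_2 0.995 0.738
```

Clustering the common part recovers the shared mixture labels (accuracy
0.995 — one boundary sample sits nearer the other component), and each
specific part recovers its own permuted labels.

The same pipeline is available from the shell:

```sh
iscluster simulate --t 10 --seed 1 --out sim/
iscluster fit --view sim/view_1.csv --view sim/view_2.csv \
    --d0 2 --d-spec 2,2 --k 2 --runs 100 --seed 1 \
    --truth-common sim/labels_common.csv --out fit/
iscluster evaluate fit/labels_common.csv sim/labels_common.csv
```

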