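"""Synthetic two-view benchmark with controllable cross-view inconsistency.

The generator draws a 2-D two-component Gaussian-mixture signal shared by
all views (the "common part"), gives each view a noisy copy of it, builds a
view-specific part by randomly permuting that copy's sample columns (so the
specific clustering structure is a scrambled image of the common one), and
mixes the stacked 4-row latent block into 8 observed features with a random
mixing matrix per view:

    X_v = P_v [Y_v ; t * T_v],    Y_v = Y + noise,  T_v = Y_v[:, perm_v].

The scale ``t`` controls how strongly the view-specific signal dominates the
shared one: small t means highly consistent views, large t means the common
structure is weak relative to the specific structure.  Ground-truth labels
are known for the common part (y) and for each specific part (y permuted by
the view's permutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import cluster_decomposition, select_beta
from .decomposition import Dimensions, ViewSet
from .metrics import c_score

__all__ = [
    "MU1",
    "MU2",
    "SIGMA",
    "SimulationBundle",
    "simulate_two_view",
    "t_ladder",
    "run_simulation_grid",
]

MU1 = np.array([-4.0, 6.0])
MU2 = np.array([3.0, -10.0])
SIGMA = np.diag([10.0, 6.0])

_T_LADDER = (0.1, 0.9, 1.0, 2.0, 5.0, 6.0, 10.0, 15.0, 20.0, 30.0)


@dataclass(frozen=True)
class SimulationBundle:
    """Generated views plus ground truth and generating parameters."""

    X: list
    y: np.ndarray
    y_spec: list
    permutations: list
    mixing: list
    t: float
    seed: int
    noise_sd: float
    orthonormal_mixing: bool = True
    latent: list = field(default_factory=list, repr=False)

    @property
    def views(self) -> ViewSet:
        return ViewSet(self.X)


def simulate_two_view(
    t: float,
    seed: int,
    n: int = 200,
    noise_sd: float = 0.1,
    n_views: int = 2,
    orthonormal_mixing: bool = True,
) -> SimulationBundle:
    """Generate the two-component mixture benchmark at inconsistency scale t.

    Draws n samples (exactly n/2 per component) from N(mu, Sigma) with
    mu1 = [-4, 6], mu2 = [3, -10], Sigma = diag(10, 6); per view adds white
    noise (sd ``noise_sd``) to form Y_v, permutes its columns uniformly at
    random to form T_v, draws an 8 x 4 mixing matrix P_v (orthonormalized by
    QR by default; raw Gaussian when ``orthonormal_mixing=False``) and emits
    ``X_v = P_v [Y_v; t T_v]`` of shape 8 x n.  Fully reproducible from seed.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n % 2 != 0 or n < 4:
        raise ValueError(f"n must be even and >= 4, got {n}")
    rng = np.random.default_rng(seed)
    half = n // 2
    Y = np.vstack(
        [
            rng.multivariate_normal(MU1, SIGMA, size=half),
            rng.multivariate_normal(MU2, SIGMA, size=half),
        ]
    ).T  # 2 x n
    y = np.repeat([1, 2], half)

    X, y_spec, perms, mixing, latent = [], [], [], [], []
    for _ in range(n_views):
        Y_v = Y + rng.normal(0.0, noise_sd, size=Y.shape)
        perm = rng.permutation(n)
        T_v = Y_v[:, perm]
        G = rng.standard_normal((8, 4))
        if orthonormal_mixing:
            Q, R = np.linalg.qr(G)
            P_v = Q * np.sign(np.diag(R))
        else:
            P_v = G
        Z_v = np.vstack([Y_v, t * T_v])
        X.append(P_v @ Z_v)
        y_spec.append(y[perm])
        perms.append(perm)
        mixing.append(P_v)
        latent.append(Z_v)
    return SimulationBundle(
        X=X,
        y=y,
        y_spec=y_spec,
        permutations=perms,
        mixing=mixing,
        t=float(t),
        seed=int(seed),
        noise_sd=float(noise_sd),
        orthonormal_mixing=orthonormal_mixing,
        latent=latent,
    )


def t_ladder() -> list:
    """The 10 inconsistency scales used by the benchmark, in increasing order."""
    return list(_T_LADDER)


def run_simulation_grid(
    t_values=None,
    seeds=(0,),
    dims: Dimensions | None = None,
    beta_grid=None,
    k: int = 2,
    runs: int = 100,
    n: int = 200,
    noise_sd: float = 0.1,
) -> pd.DataFrame:
    """Full benchmark sweep: generate, fit with beta selection, cluster, score.

    For each (t, seed): generate a bundle, select beta on the silhouette
    grid, cluster common and specific parts against their own ground truths,
    and compute the per-view consensus scores.  Returns a tidy frame with one
    row per (t, seed, representation); consensus scores are attached to the
    specific_v rows (they are per-view quantities).
    """
    if t_values is None:
        t_values = t_ladder()
    if dims is None:
        dims = Dimensions(d0=2, d_spec=(2, 2))
    rows = []
    for t in t_values:
        for seed in seeds:
            bundle = simulate_two_view(t, seed, n=n, noise_sd=noise_sd)
            views = bundle.views
            beta, dec = select_beta(
                views, dims, beta_grid=beta_grid, k=k, runs=runs, seed=seed
            )
            outcomes = cluster_decomposition(
                dec,
                k,
                runs,
                seed,
                truth_common=bundle.y,
                truth_specific=bundle.y_spec,
            )
            cs = {
                v: c_score(bundle.X[v], dec.C, dec.S[v])
                for v in range(views.V)
                if dec.S[v].shape[0] > 0
            }
            for o in outcomes:
                v = None if o.source == "common" else int(o.source.split("_")[1]) - 1
                rows.append(
                    {
                        "t": t,
                        "seed": seed,
                        "beta": beta,
                        "source": o.source,
                        "nmi": o.mean_metrics.nmi if o.mean_metrics else np.nan,
                        "acc": o.mean_metrics.acc if o.mean_metrics else np.nan,
                        "ari": o.mean_metrics.ari if o.mean_metrics else np.nan,
                        "silhouette": o.silhouette,
                        "c_score": cs.get(v, np.nan) if v is not None else np.nan,
                    }
                )
    return pd.DataFrame(rows)
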