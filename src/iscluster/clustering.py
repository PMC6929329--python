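"""Repeated k-means on fitted representations, metric averaging and model
selection.

The sample representations produced by the decomposition (the common part C
and each specific part S_v) are clustered with k-means.  Because k-means is
sensitive to its initialization, each representation is clustered ``runs``
times with seeds derived deterministically from one master seed and the
evaluation metrics are averaged over runs; the silhouette score, which needs
no ground truth, doubles as the model-selection criterion both across
representations (``select_best``) and across the HSIC weight grid
(``select_beta``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from .decomposition import Decomposition, Dimensions, ViewSet, fit_isc
from .metrics import MetricReport, _silhouette_from_distances, acc, ari, nmi

__all__ = [
    "BETA_GRID",
    "ClusteringOutcome",
    "repeated_kmeans",
    "cluster_decomposition",
    "select_best",
    "select_beta",
]

logger = logging.getLogger(__name__)

#: Default HSIC-weight grid: {0} plus the 13 powers of ten from 1e-6 to 1e6.
BETA_GRID: tuple = (0.0,) + tuple(10.0**e for e in range(-6, 7))


@dataclass(frozen=True)
class ClusteringOutcome:
    """Averaged clustering result for one representation.

    source : 'common' or 'specific_v' (1-based view index);
    labels : representative labeling (the minimum-inertia run);
    mean_metrics : NMI/ACC/ARI averaged over runs, or None without truth;
    silhouette : silhouette score averaged over runs;
    runs : number of k-means restarts averaged over.
    """

    source: str
    labels: np.ndarray
    mean_metrics: MetricReport | None
    silhouette: float
    runs: int


def _run_seeds(seed: int, runs: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(runs) % (2**31)


def repeated_kmeans(
    rep: np.ndarray,
    k: int,
    runs: int = 100,
    seed: int = 0,
    truth=None,
    source: str = "common",
) -> ClusteringOutcome:
    """Cluster the n columns of a d x n representation ``runs`` times.

    Each run is one Lloyd k-means fit with k-means++ seeding (restart
    diversity comes from the repeated outer runs).  Metrics against ``truth``
    (when given) and the silhouette score are arithmetic means over runs; the
    representative labels come from the run with the lowest within-cluster
    sum of squares.  A zero-variance representation yields the all-one-cluster
    outcome with silhouette 0.
    """
    rep = np.atleast_2d(np.asarray(rep, dtype=float))
    n = rep.shape[1]
    if k < 2:
        raise ValueError("k must be >= 2")
    if runs < 1:
        raise ValueError("runs must be >= 1")
    if k > n:
        raise ValueError(f"k = {k} exceeds sample count n = {n}")
    if truth is not None:
        truth = np.asarray(truth).ravel()
        if truth.shape[0] != n:
            raise ValueError("truth labels length mismatch")

    data = np.ascontiguousarray(rep.T)
    if np.ptp(data, axis=0).max(initial=0.0) == 0.0:
        labels = np.zeros(n, dtype=int)
        metrics = None
        if truth is not None:
            metrics = MetricReport(
                nmi=nmi(labels, truth), acc=acc(labels, truth), ari=ari(labels, truth)
            )
        return ClusteringOutcome(source, labels, metrics, 0.0, runs)

    dist = squareform(pdist(data))
    best_labels, best_inertia = None, np.inf
    sil_sum = 0.0
    metric_sums = np.zeros(3)
    for rs in _run_seeds(seed, runs):
        km = KMeans(n_clusters=k, n_init=1, random_state=int(rs)).fit(data)
        labels = km.labels_.astype(int)
        sil_sum += _silhouette_from_distances(dist, labels)
        if truth is not None:
            metric_sums += (nmi(labels, truth), acc(labels, truth), ari(labels, truth))
        if km.inertia_ < best_inertia:
            best_inertia, best_labels = km.inertia_, labels
    metrics = None
    if truth is not None:
        m = metric_sums / runs
        metrics = MetricReport(nmi=float(m[0]), acc=float(m[1]), ari=float(m[2]))
    return ClusteringOutcome(source, best_labels, metrics, sil_sum / runs, runs)


def cluster_decomposition(
    dec: Decomposition,
    k: int,
    runs: int = 100,
    seed: int = 0,
    truth_common=None,
    truth_specific=None,
) -> list:
    """Cluster the common part and every specific part of a decomposition.

    Returns one outcome per representation, tagged 'common' and
    'specific_1' .. 'specific_V'; specific parts are evaluated against their
    own per-view truths when ``truth_specific`` (a sequence) is given.  Views
    with no specific dimensions are skipped with a log note.
    """
    sub = np.random.SeedSequence(seed).generate_state(1 + len(dec.S)) % (2**31)
    outcomes = [
        repeated_kmeans(dec.C, k, runs, int(sub[0]), truth_common, source="common")
    ]
    for v, S_v in enumerate(dec.S):
        if S_v.shape[0] == 0:
            logger.info("view %d has no specific dimensions; outcome omitted", v + 1)
            continue
        truth_v = None
        if truth_specific is not None:
            truth_v = truth_specific[v]
        outcomes.append(
            repeated_kmeans(
                S_v, k, runs, int(sub[v + 1]), truth_v, source=f"specific_{v + 1}"
            )
        )
    return outcomes


def _source_rank(source: str) -> int:
    if source == "common":
        return 0
    return int(source.split("_")[1])


def select_best(outcomes: list) -> ClusteringOutcome:
    """Outcome with the highest silhouette; ties prefer the common part,
    then the lowest view index."""
    if not outcomes:
        raise ValueError("no outcomes to select from")
    return min(outcomes, key=lambda o: (-o.silhouette, _source_rank(o.source)))


def select_beta(
    views: ViewSet,
    dims_base: Dimensions,
    beta_grid=None,
    k: int = 2,
    runs: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
    recon_tol: float = 10.0,
):
    """Grid-search the HSIC weight beta by silhouette.

    Fits the decomposition for each beta in the grid, clusters every
    representation, and returns ``(beta, Decomposition)`` for the beta whose
    best outcome (per :func:`select_best`) has the highest silhouette; ties
    keep the earliest grid entry.  Deterministic given the seed.

    The penalty is a regularizer of the decomposition, not a substitute for
    it: a beta so large that the fit stops reconstructing the data produces
    representations whose silhouettes are no longer comparable.  Grid entries
    whose reconstruction error exceeds ``recon_tol`` times the best error
    achieved anywhere on the grid (plus a tiny absolute slack for exact fits)
    are therefore excluded from the silhouette comparison.
    """
    grid = BETA_GRID if beta_grid is None else tuple(beta_grid)
    if not grid:
        raise ValueError("beta grid is empty")
    energy = sum(float(np.sum(X * X)) for X in views.views)
    fits = []
    for beta in grid:
        dec = fit_isc(views, dims_base.replace_beta(beta), max_iter=max_iter, tol=tol)
        recon = sum(
            float(np.sum((views[v] - dec.reconstruct(v)) ** 2))
            for v in range(views.V)
        )
        fits.append((beta, dec, recon))
    admissible_cap = min(r for _, _, r in fits) * recon_tol + 1e-12 * energy
    best = None
    for beta, dec, recon in fits:
        if recon > admissible_cap:
            logger.debug("beta=%g excluded (recon %.3g > cap %.3g)", beta, recon, admissible_cap)
            continue
        outcomes = cluster_decomposition(dec, k, runs, seed)
        sil = select_best(outcomes).silhouette
        logger.debug("beta=%g best silhouette=%.4f", beta, sil)
        if best is None or sil > best[0]:
            best = (sil, beta, dec)
    return best[1], best[2]
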