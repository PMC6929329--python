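"""Clustering evaluation metrics and the per-view consensus score.

Implements the four measures used to judge clusterings of multi-view data —
normalized mutual information (NMI, log base 2), average clustering accuracy
(ACC, after optimal one-to-one cluster matching), the adjusted Rand index
(ARI) in its pair-counting form, and the silhouette score — plus the
consensus score (C-score) that quantifies how much of a view's centered
similarity structure is carried by the common representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb

__all__ = ["MetricReport", "nmi", "acc", "ari", "silhouette", "c_score"]


@dataclass(frozen=True)
class MetricReport:
    """NMI / ACC / ARI of a predicted labeling against a reference."""

    nmi: float
    acc: float
    ari: float


def _check_labels(pred, truth) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape[0] != truth.shape[0]:
        raise ValueError(
            f"label length mismatch: {pred.shape[0]} vs {truth.shape[0]}"
        )
    if pred.shape[0] < 1:
        raise ValueError("labels must be non-empty")
    return pred, truth


def _contingency(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Cluster-by-cluster count table n_ij."""
    _, pi = np.unique(pred, return_inverse=True)
    _, ti = np.unique(truth, return_inverse=True)
    kp, kt = pi.max() + 1, ti.max() + 1
    table = np.zeros((kp, kt), dtype=np.int64)
    np.add.at(table, (pi, ti), 1)
    return table


def nmi(pred, truth) -> float:
    """Normalized mutual information, ``2 MI / (H_pred + H_truth)``, log base 2.

    Returns 1 when both partitions are single-cluster (identical trivial
    partitions) and 0 when exactly one of them is (the printed formula is
    0/0 there; these conventions keep the score total).
    """
    pred, truth = _check_labels(pred, truth)
    n = pred.shape[0]
    table = _contingency(pred, truth)
    p_ij = table / n
    p_i = p_ij.sum(axis=1)
    p_j = p_ij.sum(axis=0)

    h_i = -np.sum(p_i * np.log2(p_i, where=p_i > 0, out=np.zeros_like(p_i)))
    h_j = -np.sum(p_j * np.log2(p_j, where=p_j > 0, out=np.zeros_like(p_j)))
    if h_i == 0.0 and h_j == 0.0:
        return 1.0
    if h_i == 0.0 or h_j == 0.0:
        return 0.0

    outer = np.outer(p_i, p_j)
    mask = p_ij > 0
    mi = float(np.sum(p_ij[mask] * np.log2(p_ij[mask] / outer[mask])))
    return 2.0 * mi / (h_i + h_j)


def acc(pred, truth) -> float:
    """Average clustering accuracy after optimal cluster-to-cluster matching.

    Predicted clusters are matched one-to-one to reference clusters by the
    linear assignment maximizing agreement (Hungarian algorithm on the
    contingency table); the score is the matched agreement fraction, so it is
    invariant to any relabeling of either argument.
    """
    pred, truth = _check_labels(pred, truth)
    table = _contingency(pred, truth)
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum()) / pred.shape[0]


def ari(pred, truth) -> float:
    """Adjusted Rand index ``(RI - E[RI]) / (max RI - E[RI])``.

    Uses the pair-counting form with RI = sum_ij C(n_ij, 2),
    max RI = (sum_i C(n_i., 2) + sum_j C(n_.j, 2)) / 2 and
    E[RI] = sum_i C(n_i., 2) * sum_j C(n_.j, 2) / C(n, 2).  In the degenerate
    case max RI == E[RI] (e.g. both partitions single-cluster) the value is 1
    for identical partitions and 0 otherwise.
    """
    pred, truth = _check_labels(pred, truth)
    n = pred.shape[0]
    if n < 2:
        raise ValueError("ARI needs at least 2 samples")
    table = _contingency(pred, truth)
    sum_ij = comb(table, 2).sum()
    sum_i = comb(table.sum(axis=1), 2).sum()
    sum_j = comb(table.sum(axis=0), 2).sum()
    expected = sum_i * sum_j / comb(n, 2)
    max_ri = 0.5 * (sum_i + sum_j)
    if max_ri == expected:
        identical = nmi(pred, truth) == 1.0 or (sum_i == sum_j == sum_ij)
        return 1.0 if identical else 0.0
    return float((sum_ij - expected) / (max_ri - expected))


def _silhouette_from_distances(dist: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette from a precomputed n x n Euclidean distance matrix."""
    n = dist.shape[0]
    uniq, inv = np.unique(labels, return_inverse=True)
    k = uniq.shape[0]
    if k < 2:
        warnings.warn("silhouette undefined for a single cluster; returning 0")
        return 0.0
    counts = np.bincount(inv, minlength=k)
    # per-sample summed distance to each cluster, n x k
    sums = np.zeros((n, k))
    for c in range(k):
        sums[:, c] = dist[:, inv == c].sum(axis=1)
    own = counts[inv]
    scores = np.zeros(n)
    nontrivial = own > 1
    a = np.zeros(n)
    a[nontrivial] = sums[np.arange(n), inv][nontrivial] / (own[nontrivial] - 1)
    other = sums / counts
    other[np.arange(n), inv] = np.inf
    b = other.min(axis=1)
    with np.errstate(invalid="ignore"):
        s = (b - a) / np.maximum(a, b)
    scores[nontrivial] = s[nontrivial]  # singleton clusters score 0
    return float(scores.mean())


def silhouette(rep: np.ndarray, labels) -> float:
    """Mean silhouette score of ``labels`` on a d x n representation.

    For sample i, a_i is the mean Euclidean distance to the other members of
    its own cluster and b_i the minimum over other clusters of the mean
    distance to that cluster's members; the per-sample score is
    ``(b_i - a_i) / max(a_i, b_i)``.  Samples in singleton clusters score 0,
    and a labeling with a single cluster overall returns 0 with a warning.
    """
    rep = np.atleast_2d(np.asarray(rep, dtype=float))
    labels = np.asarray(labels).ravel()
    n = rep.shape[1]
    if labels.shape[0] != n:
        raise ValueError(f"labels length {labels.shape[0]} != sample count {n}")
    if n < 2:
        raise ValueError("silhouette needs at least 2 samples")
    dist = squareform(pdist(rep.T))
    return _silhouette_from_distances(dist, labels)


def c_score(view: np.ndarray, C: np.ndarray, S_v: np.ndarray) -> float:
    """Consensus score of one view given its common and specific parts.

    ``tr(H X^T X H C^T C) / tr(H X^T X H (C^T C + S^T S))`` with H the sample
    centering matrix; equals the fraction of the view's centered similarity
    structure explained by the common representation, in [0, 1].  Higher
    values mean stronger cross-view consistency in this view.

    Raises
    ------
    ValueError
        If sample counts disagree or the denominator vanishes (both C and
        S_v constant across samples), where the ratio is undefined.
    """
    X = np.atleast_2d(np.asarray(view, dtype=float))
    C = np.atleast_2d(np.asarray(C, dtype=float))
    S = np.atleast_2d(np.asarray(S_v, dtype=float))
    n = X.shape[1]
    if C.shape[1] != n or S.shape[1] != n:
        raise ValueError("view, C and S_v must share the sample count")
    Xc = X - X.mean(axis=1, keepdims=True)
    # tr(Xc^T Xc M^T M) = ||Xc M^T||_F^2 for any representation M
    num = float(np.sum((Xc @ C.T) ** 2))
    spec = float(np.sum((Xc @ S.T) ** 2))
    den = num + spec
    scale = float(np.sum(Xc * Xc)) * float(np.sum(C * C) + np.sum(S * S))
    if den <= 1e-12 * scale or scale == 0.0:
        raise ValueError(
            "C-score undefined: representations carry no centered structure "
            "(both constant across samples)"
        )
    return num / den
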