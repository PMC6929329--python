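"""Common/specific subspace decomposition of multi-view data.

Each of V views ``X_v`` (p_v features x n shared samples) is modelled as

    X_v = P_v [C; S_v] + E_v,      P_v^T P_v = I,

where ``C`` (d0 x n) is a representation of the samples shared by every view
and ``S_v`` (d_v x n) is specific to view v; the orthonormal basis ``P_v``
splits column-wise into a common block (first d0 columns) and a specific
block, so the two parts live in orthogonal subspaces of view v's feature
space.  The fitted objective is

    sum_v ||X_v - P_v [C; S_v]||_F^2  +  beta * sum_v tr(C^T C H S_v^T S_v H),

i.e. reconstruction error plus a linear-kernel HSIC penalty discouraging
statistical dependence between the common and specific representations.

The optimizer alternates three exact block updates, each of which can only
decrease the objective:

1. each ``S_v`` solves a Sylvester-type stationarity equation (which reduces
   to a single symmetric linear system because ``P_v`` is orthonormal);
2. each ``P_v`` is the closed-form orthogonal Procrustes solution, the thin
   SVD of ``X_v [C; S_v]^T``;
3. ``C`` solves the analogous pooled Sylvester equation across views.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .kernels import centering_matrix

__all__ = [
    "ViewSet",
    "Dimensions",
    "Decomposition",
    "objective",
    "solve_specific",
    "solve_basis",
    "solve_common",
    "fit_isc",
]

_RANK_TOL = 1e-12


@dataclass(frozen=True)
class ViewSet:
    """Ordered collection of feature x sample matrices sharing n samples."""

    views: list

    def __post_init__(self):
        mats = [np.atleast_2d(np.asarray(X, dtype=float)) for X in self.views]
        if not mats:
            raise ValueError("ViewSet needs at least one view")
        n = mats[0].shape[1]
        for i, X in enumerate(mats):
            if X.ndim != 2:
                raise ValueError(f"view {i} is not a matrix")
            if X.shape[1] != n:
                raise ValueError(
                    f"view {i} has {X.shape[1]} samples, expected {n}"
                )
            if X.shape[0] < 1:
                raise ValueError(f"view {i} has no features")
            if not np.all(np.isfinite(X)):
                raise ValueError(f"view {i} contains non-finite entries")
        if n < 2:
            raise ValueError(f"need at least 2 samples, got {n}")
        object.__setattr__(self, "views", mats)

    @property
    def n(self) -> int:
        return self.views[0].shape[1]

    @property
    def V(self) -> int:
        return len(self.views)

    @property
    def p(self) -> list:
        return [X.shape[0] for X in self.views]

    def __getitem__(self, v: int) -> np.ndarray:
        return self.views[v]


@dataclass(frozen=True)
class Dimensions:
    """Subspace dimensions and penalty weight for a decomposition.

    d0 : common dimension (>= 1);
    d_spec : per-view specific dimensions (>= 0);
    beta : nonnegative HSIC penalty weight.
    """

    d0: int
    d_spec: tuple
    beta: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "d_spec", tuple(int(d) for d in self.d_spec))
        if self.d0 < 1:
            raise ValueError(f"d0 must be >= 1, got {self.d0}")
        if any(d < 0 for d in self.d_spec):
            raise ValueError(f"specific dimensions must be >= 0: {self.d_spec}")
        if not np.isfinite(self.beta) or self.beta < 0:
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")

    def validate_for(self, views: ViewSet) -> None:
        if len(self.d_spec) != views.V:
            raise ValueError(
                f"{len(self.d_spec)} specific dimensions for {views.V} views"
            )
        for v, (d_v, p_v) in enumerate(zip(self.d_spec, views.p)):
            if self.d0 + d_v > p_v:
                raise ValueError(
                    f"view {v}: d0 + d_v = {self.d0 + d_v} exceeds p_v = {p_v}"
                )

    def replace_beta(self, beta: float) -> "Dimensions":
        return Dimensions(self.d0, self.d_spec, beta)


@dataclass
class Decomposition:
    """Fitted bases and representations.

    ``P[v]`` is the orthonormal p_v x (d0 + d_v) basis of view v whose first
    d0 columns span the common subspace, ``C`` the d0 x n common
    representation, ``S[v]`` the d_v x n specific representation.
    """

    P: list
    C: np.ndarray
    S: list
    d0: int
    objective_trace: list = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    def P_common(self, v: int) -> np.ndarray:
        return self.P[v][:, : self.d0]

    def P_specific(self, v: int) -> np.ndarray:
        return self.P[v][:, self.d0 :]

    def Z(self, v: int) -> np.ndarray:
        return np.vstack([self.C, self.S[v]])

    def reconstruct(self, v: int) -> np.ndarray:
        return self.P[v] @ self.Z(v)

    def orthonormality_defect(self) -> float:
        """max_v ||P_v^T P_v - I||_max; ~0 for a valid decomposition."""
        return max(
            float(np.abs(P.T @ P - np.eye(P.shape[1])).max()) for P in self.P
        )


def _as_parts(views, dec):
    Xs = views.views if isinstance(views, ViewSet) else list(views)
    return Xs, dec.P, dec.C, dec.S


def objective(views: ViewSet, dec: Decomposition, dims: Dimensions) -> float:
    """Evaluate the fitted objective: reconstruction + beta * HSIC penalty."""
    Xs, P, C, S = _as_parts(views, dec)
    beta = dims.beta
    n = C.shape[1]
    Cc = C - C.mean(axis=1, keepdims=True)
    total = 0.0
    for X, P_v, S_v in zip(Xs, P, S):
        Z = np.vstack([C, S_v])
        if X.shape[1] != n or P_v.shape != (X.shape[0], Z.shape[0]):
            raise ValueError("inconsistent shapes in objective evaluation")
        R = X - P_v @ Z
        total += float(np.sum(R * R))
        if beta > 0 and S_v.shape[0] > 0:
            Sc = S_v - S_v.mean(axis=1, keepdims=True)
            cross = Cc @ Sc.T
            total += beta * float(np.sum(cross * cross))
    if not np.isfinite(total):
        raise ValueError("objective is not finite")
    return total


def solve_specific(
    view_index: int,
    views: ViewSet,
    dec: Decomposition,
    dims: Dimensions,
    method: str = "reduced",
) -> np.ndarray:
    """Optimal ``S_v`` with all other blocks fixed.

    Solves the stationarity equation

        (P_s^T P_s) S_v + beta S_v (H C^T C H) = P_s^T X_v - P_s^T P_c C,

    a Sylvester equation whose left coefficient is the identity because
    ``P_v`` has orthonormal columns, so the reduced path is the single
    symmetric solve ``S_v (I + beta H C^T C H) = RHS``.  ``method='sylvester'``
    uses the general Bartels–Stewart solver instead (kept for cross-checks).
    """
    X = views[view_index]
    P_c = dec.P_common(view_index)
    P_s = dec.P_specific(view_index)
    C = dec.C
    n = X.shape[1]
    rhs = P_s.T @ X - (P_s.T @ P_c) @ C
    if P_s.shape[1] == 0:
        return np.zeros((0, n))
    # H C^T C H = (C H)^T (C H): center columns instead of multiplying by H
    Cc = C - C.mean(axis=1, keepdims=True)
    B = dims.beta * (Cc.T @ Cc)
    if method == "sylvester":
        A = P_s.T @ P_s
        H = centering_matrix(n)
        return linalg.solve_sylvester(A, dims.beta * (H @ (C.T @ C) @ H), rhs)
    # S (I + B) = rhs with I + B symmetric positive definite
    M = np.eye(n) + B
    return linalg.solve(M, rhs.T, assume_a="pos").T


def solve_basis(view_index: int, views: ViewSet, dec: Decomposition) -> np.ndarray:
    """Optimal orthonormal basis ``P_v`` with ``Z_v = [C; S_v]`` fixed.

    Minimizing ``||X_v - P_v Z_v||_F^2`` over matrices with orthonormal
    columns is the orthogonal Procrustes problem: with thin SVD
    ``X_v Z_v^T = U diag(s) V^T`` the minimizer is ``U V^T``.  When the
    product is rank-deficient the optimum is non-unique; the SVD factors
    provide a deterministic orthonormal completion and a warning is issued.
    """
    X = views[view_index]
    Z = dec.Z(view_index)
    M = X @ Z.T
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    if s.size and s[-1] <= s[0] * _RANK_TOL:
        warnings.warn(
            f"view {view_index}: X_v Z_v^T is rank-deficient; "
            "basis completed deterministically from the SVD factors"
        )
    return U @ Vt


def solve_common(
    views: ViewSet,
    dec: Decomposition,
    dims: Dimensions,
    method: str = "reduced",
) -> np.ndarray:
    """Optimal common representation ``C`` with all ``P_v``, ``S_v`` fixed.

    Solves the pooled stationarity equation

        (sum_v P_c^T P_c) C + beta C (sum_v H S_v^T S_v H)
            = sum_v (P_c^T X_v - P_c^T P_s S_v),

    whose left coefficient is ``V * I`` by orthonormality; the reduced path
    is one symmetric solve, with a general Sylvester path for cross-checks.
    """
    n = views.n
    rhs = np.zeros((dims.d0, n))
    B = np.zeros((n, n))
    A = np.zeros((dims.d0, dims.d0))
    for v in range(views.V):
        P_c = dec.P_common(v)
        P_s = dec.P_specific(v)
        S_v = dec.S[v]
        rhs += P_c.T @ views[v] - (P_c.T @ P_s) @ S_v
        A += P_c.T @ P_c
        if dims.beta > 0 and S_v.shape[0] > 0:
            Sc = S_v - S_v.mean(axis=1, keepdims=True)
            B += Sc.T @ Sc  # = H S_v^T S_v H
    B *= dims.beta
    if method == "sylvester":
        return linalg.solve_sylvester(A, B, rhs)
    M = views.V * np.eye(n) + B
    return linalg.solve(M, rhs.T, assume_a="pos").T


def _svd_init(views: ViewSet, dims: Dimensions):
    P = []
    for v in range(views.V):
        d = dims.d0 + dims.d_spec[v]
        U, _, _ = np.linalg.svd(views[v], full_matrices=False)
        if U.shape[1] < d:  # thin SVD has min(p_v, n) columns; complete by QR
            Q, _ = np.linalg.qr(np.hstack([U, np.eye(views[v].shape[0])]))
            U = Q
        P.append(U[:, :d])
    return P


def _random_init(views: ViewSet, dims: Dimensions, rng: np.random.Generator):
    P = []
    for v in range(views.V):
        d = dims.d0 + dims.d_spec[v]
        G = rng.standard_normal((views.p[v], d))
        Q, R = np.linalg.qr(G)
        P.append(Q * np.sign(np.diag(R)))
    return P


def _fit_from(views, dims, P, max_iter, tol, method) -> Decomposition:
    """Run the alternating scheme from initial bases P until tolerance."""
    # warm-start representations by projection onto the initial bases
    proj = [P[v].T @ views[v] for v in range(views.V)]
    C = np.mean([pr[: dims.d0] for pr in proj], axis=0)
    S = [proj[v][dims.d0 :] for v in range(views.V)]

    dec = Decomposition(P=P, C=C, S=S, d0=dims.d0)
    trace = [objective(views, dec, dims)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for v in range(views.V):
            dec.S[v] = solve_specific(v, views, dec, dims, method=method)
        for v in range(views.V):
            dec.P[v] = solve_basis(v, views, dec)
        dec.C = solve_common(views, dec, dims, method=method)
        f = objective(views, dec, dims)
        trace.append(f)
        if abs(trace[-2] - f) / max(1.0, trace[-2]) < tol:
            converged = True
            break
    dec.objective_trace = trace
    dec.converged = converged
    dec.iterations = it
    return dec


def fit_isc(
    views: ViewSet,
    dims: Dimensions,
    max_iter: int = 100,
    tol: float = 1e-6,
    init: str = "svd",
    seed: int | None = 0,
    method: str = "reduced",
    n_init: int = 3,
) -> Decomposition:
    """Fit the common/specific decomposition by alternating exact updates.

    Per outer iteration: update every ``S_v`` (Sylvester step), every ``P_v``
    (Procrustes step), then ``C`` (pooled Sylvester step); each step exactly
    minimizes the objective over its block, so the recorded objective trace
    is non-increasing.  Stops when the relative objective decrease
    ``|f_k - f_{k-1}| / max(1, f_{k-1})`` falls below ``tol``.

    The alternating scheme can land in poor local minima (typically with the
    common and specific roles swapped), so the fit is restarted from several
    initializations and the run with the lowest final objective is kept —
    deterministic given ``seed``.

    Parameters
    ----------
    init : 'svd' starts run 1 from the top left singular vectors of each
        view (deterministic warm start) and the remaining runs from seeded
        random orthonormal bases; 'random' uses random bases for all runs.
    n_init : number of restarts (>= 1).
    seed : seeds the random initializations.
    method : 'reduced' (identity-coefficient linear solves) or 'sylvester'
        (general Bartels–Stewart solver); the two agree to solver precision.
    """
    if not isinstance(views, ViewSet):
        views = ViewSet(list(views))
    dims.validate_for(views)
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if n_init < 1:
        raise ValueError("n_init must be >= 1")
    if init not in {"svd", "random"}:
        raise ValueError(f"unknown init {init!r}")

    rng = np.random.default_rng(seed)
    best = None
    for r in range(n_init):
        if r == 0 and init == "svd":
            P = _svd_init(views, dims)
        else:
            P = _random_init(views, dims, rng)
        dec = _fit_from(views, dims, P, max_iter, tol, method)
        if best is None or dec.objective_trace[-1] < best.objective_trace[-1]:
            best = dec
    return best
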