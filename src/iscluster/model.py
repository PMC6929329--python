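"""Model/results facade over the decomposition, clustering and scoring layers.

``ISCModel`` is built from the view matrices (or DataFrames) and holds the
model configuration (subspace dimensions, HSIC weight); ``fit`` returns an
``ISCResults`` carrying the fitted bases and representations together with
diagnostics, clustering helpers and a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import cluster_decomposition, select_beta
from .decomposition import Decomposition, Dimensions, ViewSet, fit_isc, objective
from .metrics import c_score

__all__ = ["ISCModel", "ISCResults"]


class ISCModel:
    """Integrative subspace clustering model for V feature x sample views.

    Parameters
    ----------
    views : sequence of array-likes, each p_v x n with a shared sample
        ordering across views (samples in columns).
    d0 : dimension of the common subspace.
    d_spec : per-view specific dimensions; a single int is broadcast to all
        views; defaults to d0 for every view.
    beta : HSIC penalty weight (>= 0).
    """

    def __init__(self, views, d0: int = 2, d_spec=None, beta: float = 1.0):
        self.views = views if isinstance(views, ViewSet) else ViewSet(list(views))
        if d_spec is None:
            d_spec = [d0] * self.views.V
        elif np.isscalar(d_spec):
            d_spec = [int(d_spec)] * self.views.V
        self.dims = Dimensions(d0=d0, d_spec=tuple(d_spec), beta=beta)
        self.dims.validate_for(self.views)

    @classmethod
    def from_dataframes(
        cls,
        frames,
        orientation: str = "samples-in-columns",
        **kwargs,
    ) -> "ISCModel":
        """Build a model from pandas DataFrames (one per view).

        ``orientation='samples-in-rows'`` transposes each frame first.  Sample
        alignment is checked through the column labels when all frames carry
        them.
        """
        mats = []
        names = None
        for i, df in enumerate(frames):
            df = pd.DataFrame(df)
            if orientation == "samples-in-rows":
                df = df.T
            elif orientation != "samples-in-columns":
                raise ValueError(f"unknown orientation {orientation!r}")
            has_names = not pd.api.types.is_integer_dtype(df.columns)
            cols = [str(c) for c in df.columns]
            if names is not None and has_names and cols != names:
                mismatch = sorted(set(cols) ^ set(names))
                raise ValueError(
                    f"view {i} sample names disagree with view 0: {mismatch[:5]}"
                )
            if names is None and has_names:
                names = cols
            mats.append(df.to_numpy(dtype=float))
        model = cls(mats, **kwargs)
        model.sample_names = names
        return model

    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-6,
        init: str = "svd",
        seed: int | None = 0,
        method: str = "reduced",
    ) -> "ISCResults":
        """Fit by alternating minimization; see :func:`fit_isc`."""
        dec = fit_isc(
            self.views,
            self.dims,
            max_iter=max_iter,
            tol=tol,
            init=init,
            seed=seed,
            method=method,
        )
        return ISCResults(self, dec, beta=self.dims.beta)

    def fit_select_beta(
        self,
        beta_grid=None,
        k: int = 2,
        runs: int = 100,
        seed: int = 0,
        max_iter: int = 100,
        tol: float = 1e-6,
    ) -> "ISCResults":
        """Fit once per beta in the grid and keep the silhouette-best fit."""
        beta, dec = select_beta(
            self.views,
            self.dims,
            beta_grid=beta_grid,
            k=k,
            runs=runs,
            seed=seed,
            max_iter=max_iter,
            tol=tol,
        )
        return ISCResults(self, dec, beta=beta)


class ISCResults:
    """Fitted decomposition with diagnostics and downstream helpers.

    Attributes
    ----------
    C : d0 x n common representation.
    S : list of d_v x n specific representations.
    P : list of orthonormal p_v x (d0 + d_v) bases.
    beta : HSIC weight of the retained fit (the selected one when the model
        was fitted over a grid).
    objective_trace : objective value at initialization and after each outer
        iteration (non-increasing).
    """

    def __init__(self, model: ISCModel, decomposition: Decomposition, beta: float):
        self.model = model
        self.decomposition = decomposition
        self.beta = float(beta)

    # -- parameter access ---------------------------------------------------
    @property
    def C(self) -> np.ndarray:
        return self.decomposition.C

    @property
    def S(self) -> list:
        return self.decomposition.S

    @property
    def P(self) -> list:
        return self.decomposition.P

    @property
    def objective_trace(self) -> list:
        return self.decomposition.objective_trace

    @property
    def converged(self) -> bool:
        return self.decomposition.converged

    @property
    def n_iter(self) -> int:
        return self.decomposition.iterations

    # -- diagnostics --------------------------------------------------------
    def objective(self) -> float:
        dims = self.model.dims.replace_beta(self.beta)
        return objective(self.model.views, self.decomposition, dims)

    def reconstruction_errors(self) -> list:
        """Per-view relative reconstruction error ||X_v - P_v Z_v|| / ||X_v||."""
        errs = []
        for v in range(self.model.views.V):
            X = self.model.views[v]
            R = X - self.decomposition.reconstruct(v)
            errs.append(float(np.linalg.norm(R) / max(np.linalg.norm(X), 1e-300)))
        return errs

    def c_scores(self) -> list:
        """Consensus score of each view (NaN for views without specific part)."""
        out = []
        for v in range(self.model.views.V):
            if self.decomposition.S[v].shape[0] == 0:
                out.append(float("nan"))
            else:
                out.append(
                    c_score(self.model.views[v], self.C, self.decomposition.S[v])
                )
        return out

    # -- downstream ---------------------------------------------------------
    def cluster(
        self,
        k: int,
        runs: int = 100,
        seed: int = 0,
        truth_common=None,
        truth_specific=None,
    ) -> list:
        """Repeated k-means on C and every S_v; see
        :func:`iscluster.clustering.cluster_decomposition`."""
        return cluster_decomposition(
            self.decomposition,
            k,
            runs=runs,
            seed=seed,
            truth_common=truth_common,
            truth_specific=truth_specific,
        )

    def summary(self) -> str:
        """Plain-text summary table of the fit."""
        views = self.model.views
        dims = self.model.dims
        lines = [
            "Integrative Subspace Clustering Results",
            "=" * 55,
            f"{'Views':<28}{views.V}",
            f"{'Samples (n)':<28}{views.n}",
            f"{'Features per view':<28}{tuple(views.p)}",
            f"{'Common dim (d0)':<28}{dims.d0}",
            f"{'Specific dims':<28}{dims.d_spec}",
            f"{'HSIC weight (beta)':<28}{self.beta:g}",
            f"{'Iterations':<28}{self.n_iter}",
            f"{'Converged':<28}{self.converged}",
            f"{'Objective':<28}{self.objective_trace[-1]:.6g}",
            "-" * 55,
        ]
        cs = self.c_scores()
        errs = self.reconstruction_errors()
        lines.append(f"{'View':<8}{'rel. recon. error':>20}{'C-score':>14}")
        for v in range(views.V):
            lines.append(f"{v + 1:<8}{errs[v]:>20.3e}{cs[v]:>14.4g}")
        lines.append("=" * 55)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ISCResults V={self.model.views.V} n={self.model.views.n} "
            f"d0={self.model.dims.d0} beta={self.beta:g} "
            f"iterations={self.n_iter} converged={self.converged}>"
        )
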