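"""Centering matrix and the linear-kernel HSIC estimator.

The Hilbert-Schmidt Independence Criterion (HSIC) measures statistical
dependence between two sample representations through their centered kernel
matrices: the empirical estimator is proportional to ``tr(K_a H K_b H)``
where ``H = I - ee^T/n`` is the centering matrix.  The decomposition
objective uses the linear-kernel form ``tr(A^T A H B^T B H)`` as a penalty
discouraging dependence between the common and view-specific representations;
this module provides exactly that trace (the proportionality constant of the
population estimator is dropped).
"""

from __future__ import annotations

import numpy as np

__all__ = ["centering_matrix", "hsic_linear"]


def centering_matrix(n: int) -> np.ndarray:
    """Return the n x n centering matrix ``H = I - ee^T / n``.

    H is symmetric, idempotent, and annihilates the all-ones vector.

    Parameters
    ----------
    n : int
        Number of samples; must be >= 1.
    """
    if n < 1:
        raise ValueError(f"centering matrix needs n >= 1, got {n}")
    return np.eye(n) - np.full((n, n), 1.0 / n)


def hsic_linear(A: np.ndarray, B: np.ndarray) -> float:
    """Empirical linear-kernel HSIC term ``tr(A^T A H B^T B H)``.

    ``A`` (d_a x n) and ``B`` (d_b x n) hold one sample per column.  With
    linear kernels ``K_a = A^T A`` and ``K_b = B^T B`` the trace equals
    ``||(A H)(B H)^T||_F^2``, which is the form evaluated here: it is
    symmetric in (A, B), nonnegative, and zero when either representation is
    constant across samples.

    Raises
    ------
    ValueError
        If the two representations have different sample counts.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2:
        raise ValueError("hsic_linear expects 2-D arrays (features x samples)")
    if A.shape[1] != B.shape[1]:
        raise ValueError(
            f"sample counts differ: A has {A.shape[1]} columns, B has {B.shape[1]}"
        )
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    cross = Ac @ Bc.T
    return float(np.sum(cross * cross))
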