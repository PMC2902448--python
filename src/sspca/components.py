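"""Choosing the number of components and variance accounting.

The number of significant components is decided by a permutation test: each
permutation independently shuffles the expression values within every sample
(row), destroying between-variable correlation while preserving each row's
marginal distribution.  The singular values of the re-centered permuted
matrices form the null; the observed ``d_k`` is significant when it exceeds
the null at level alpha (add-one corrected p-values, never exactly zero).
``k0`` is the largest k whose leading k singular values are all significant.

Sparse principal component scores are generally correlated, so naive
per-component variances over-count.  The adjusted variance of component k is
the squared k-th diagonal of the R factor of a QR decomposition of the score
matrix divided by n -- the variance genuinely added by component k after
projecting out the preceding ones -- reported as a percent of the total
variance.  For ordinary PCA (orthogonal scores) it coincides with the usual
explained variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray

__all__ = ["PermutationResult", "permutation_component_count", "adjusted_variance"]


@dataclass(frozen=True)
class PermutationResult:
    """Observed spectrum, permutation null and the selected component count."""

    d_observed: NDArray[np.float64]
    perm_null: NDArray[np.float64]  # P x k matrix of permuted singular values
    p_values: NDArray[np.float64]
    k0: int
    P: int
    alpha: float


def _values(X) -> NDArray[np.float64]:
    return np.asarray(getattr(X, "values", X), dtype=float)


def permutation_component_count(
    X, P: int = 1000, alpha: float = 0.001, seed: int = 0
) -> PermutationResult:
    """Permutation test for the number of significant principal components.

    p-value of ``d_k`` is ``(1 + #{permuted d_k >= observed d_k}) / (P + 1)``;
    ``k0 = max{k : p_j < alpha for all j <= k}`` (0 if the first component is
    already insignificant).
    """
    if P < 1:
        raise ValueError("P must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    A = _values(X)
    A = A - A.mean(axis=0)
    d_obs = np.linalg.svd(A, compute_uv=False)
    k = d_obs.size
    rng = np.random.default_rng(seed)
    null = np.empty((P, k))
    for b in range(P):
        perm = rng.permuted(A, axis=1)  # shuffle within each sample (row)
        perm = perm - perm.mean(axis=0)  # permuting rows moves column means
        null[b] = np.linalg.svd(perm, compute_uv=False)
    p_values = (1.0 + np.sum(null >= d_obs, axis=0)) / (P + 1.0)
    k0 = 0
    for j in range(k):
        if p_values[j] < alpha:
            k0 = j + 1
        else:
            break
    return PermutationResult(
        d_observed=d_obs, perm_null=null, p_values=p_values, k0=k0, P=P, alpha=alpha
    )


def adjusted_variance(
    X, loadings: NDArray[np.float64]
) -> tuple[NDArray[np.float64], NDArray[np.float64]]:
    """Adjusted and cumulative adjusted variance (percent of total).

    ``loadings`` columns must be unit-norm.  Returns ``(adj, cum)`` where
    ``adj[k] = R[k, k]**2 / n`` from the QR decomposition of ``Z = X @
    loadings``, as a percent of ``trace(S_X)``.  Rank-deficient score
    matrices yield zero adjusted variance for the redundant directions.
    """
    A = _values(X)
    L = np.asarray(loadings, dtype=float)
    if L.ndim == 1:
        L = L[:, None]
    norms = np.linalg.norm(L, axis=0)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("loading columns must be unit-norm")
    n = A.shape[0]
    total = np.sum(A * A) / n  # trace of S_X
    Z = A @ L
    R = np.linalg.qr(Z, mode="r")
    adj = np.diag(R) ** 2 / n
    adj_pct = 100.0 * adj / total
    return adj_pct, np.cumsum(adj_pct)
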